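"""Figure-copy scoring (4-pointed star and diamond-with-midline).

The patient's freehand copy is isolated inside the template's drawing
region, its corners are detected on the outline, an idealized archetype is
anchored to the detected corners, and the drawing is scored on three binary
attributes — shape (gestalt), details, arrangement — plus the BIT-style
binary completeness score.

Corner detection uses a radial outline profile: the maximum ink radius per
angular bin around the drawing's centroid.  Local maxima of the profile are
outer tips (star) or diamond corners; local minima between consecutive tips
are the star's inner vertices.  This behaves identically for closed and
open drawings (missing tips, gapped edges), which the degraded-drawing
failure modes require.  Edge presence is decided by ink coverage inside a
corridor along each archetype edge, with a closure-gap tolerance; angles
are measured from principal-axis line fits to the edge ink, giving
sub-degree accuracy independent of single-pixel corner localization.

Scoring thresholds (100 px radial consistency, exactly 8 corners, 200 px
span/alignment, 100 px intermediate spacing, 110° ± 40°/30° tip angles for
the star; 45° ± 7° midline angles with at most one violation for the
diamond) are expressed in canonical pixels and degrees and live in
:class:`~neglectscore.config.PipelineConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .layout import LayoutTemplate
from .pipeline import InkMask


# ---------------------------------------------------------------------------
# criteria containers
# ---------------------------------------------------------------------------

@dataclass
class StarCriteria:
    max_radial_deviation: float = 100.0
    required_corners: int = 8
    span_difference_max: float = 200.0
    tip_misalignment_max: float = 200.0
    intermediate_distance_deviation_max: float = 100.0
    angle_deviation_max: float = 40.0
    angle_deviation_strict: float = 30.0
    expected_angle: float = 110.0
    min_angles_within_strict: int = 2

    def __post_init__(self):
        if self.angle_deviation_strict > self.angle_deviation_max:
            raise ValueError("strict tolerance must not exceed the maximum")

    @classmethod
    def from_config(cls, c: PipelineConfig) -> "StarCriteria":
        return cls(c.star_max_radial_deviation, c.star_required_corners,
                   c.star_span_difference_max, c.star_tip_misalignment_max,
                   c.star_intermediate_distance_deviation_max,
                   c.star_angle_deviation_max, c.star_angle_deviation_strict,
                   c.star_expected_angle, c.star_min_angles_within_strict)


@dataclass
class DiamondCriteria:
    expected_half_angle: float = 45.0
    angle_tolerance: float = 7.0
    max_violations_allowed: int = 1
    require_all_outer_edges: bool = True
    require_midline: bool = True

    @classmethod
    def from_config(cls, c: PipelineConfig) -> "DiamondCriteria":
        return cls(c.diamond_expected_half_angle, c.diamond_angle_tolerance,
                   c.diamond_max_violations_allowed)


@dataclass
class CornerSet:
    """Detected corners ordered angularly around the drawing centroid."""
    corners: list[tuple[float, float]]
    classes: list[str]                  # 'outer' | 'inner' | 'corner'
    centroid: Optional[tuple[float, float]]
    angles_deg: list[float]             # angular position of each corner

    def __len__(self) -> int:
        return len(self.corners)

    def of_class(self, cls: str) -> list[tuple[float, float]]:
        return [p for p, c in zip(self.corners, self.classes) if c == cls]


@dataclass
class Archetype:
    figure: str                          # 'star' | 'diamond'
    vertices: list[tuple[float, float]]  # ordered polygon vertices
    midline: Optional[tuple[tuple[float, float], tuple[float, float]]] = None
    degenerate: bool = False


@dataclass
class CopyScore:
    shape: int = 0
    detail: int = 0
    arrangement: int = 0
    net_sum: int = 0
    net_hierarchical: int = 0
    bit_binary: int = 0
    standard_value: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def finalize(self) -> "CopyScore":
        self.net_sum = self.shape + self.detail + self.arrangement
        d = self.detail if self.shape else 0
        a = self.arrangement if (self.shape and d) else 0
        self.net_hierarchical = self.shape + d + a
        self.bit_binary = int(bool(self.shape and self.detail))
        return self


# ---------------------------------------------------------------------------
# drawing extraction / corner detection
# ---------------------------------------------------------------------------

def _region_points(ink: InkMask, region) -> np.ndarray:
    x0, y0, x1, y1 = region
    sub = ink.mask[int(y0):int(y1), int(x0):int(x1)]
    ys, xs = np.nonzero(sub)
    return np.column_stack([xs + int(x0), ys + int(y0)]).astype(np.float64)


def _circular_peaks(profile: np.ndarray, prominence: float,
                    min_sep_bins: int) -> list[int]:
    """Indices of circular local maxima with the given prominence."""
    from scipy.signal import find_peaks
    n = profile.size
    tiled = np.concatenate([profile, profile, profile])
    idx, _ = find_peaks(tiled, prominence=prominence, distance=min_sep_bins)
    peaks = sorted({i - n for i in idx if n <= i < 2 * n})
    return [p for p in peaks if 0 <= p < n]


def _fill_empty_circular(rmax: np.ndarray) -> np.ndarray:
    """Linearly interpolate the radial profile across empty (ink-free) bins.

    Stroke gaps leave empty bins whose hard zeros would turn every stroke
    end into a spurious peak; interpolation bridges them without creating
    local maxima inside the gap.
    """
    n = rmax.size
    filled = np.flatnonzero(rmax > 0)
    if filled.size == 0 or filled.size == n:
        return rmax.copy()
    out = rmax.copy()
    for k in np.flatnonzero(rmax == 0):
        prev = filled[filled < k]
        nxt = filled[filled > k]
        lo = prev[-1] if prev.size else filled[-1] - n
        hi = nxt[0] if nxt.size else filled[0] + n
        w = (k - lo) / (hi - lo)
        out[k] = (1 - w) * rmax[lo % n] + w * rmax[hi % n]
    return out


def _line_intersection(p1, d1, p2, d2) -> Optional[np.ndarray]:
    """Intersection of two parametric lines, None when near-parallel."""
    mat = np.column_stack([d1, -d2])
    det = float(np.linalg.det(mat))
    if abs(det) < 1e-6:
        return None
    t = np.linalg.solve(mat, np.asarray(p2, float) - np.asarray(p1, float))
    return np.asarray(p1, float) + t[0] * np.asarray(d1, float)


def extract_drawing(ink: InkMask, region, figure: str,
                    config: PipelineConfig = DEFAULT_CONFIG
                    ) -> tuple[np.ndarray, CornerSet]:
    """Ink points inside the drawing region plus the detected corner set.

    An empty region yields an empty :class:`CornerSet` (downstream scores
    are 0, never an error).
    """
    pts = _region_points(ink, region)
    if pts.shape[0] < 30:
        return pts, CornerSet([], [], None, [])
    cx, cy = pts.mean(axis=0)
    dx = pts[:, 0] - cx
    dy = pts[:, 1] - cy
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(-dy, dx)) % 360.0

    nbins = config.copy_radial_bins
    bin_w = 360.0 / nbins
    bins = np.minimum((theta / bin_w).astype(int), nbins - 1)
    rmax = np.zeros(nbins)
    np.maximum.at(rmax, bins, r)

    profile = _fill_empty_circular(rmax)
    prom = config.copy_peak_prominence * float(profile.max())
    sep = max(int(config.copy_peak_separation_deg / bin_w), 1)
    peak_bins = _circular_peaks(profile, prom, sep)
    if not peak_bins:
        return pts, CornerSet([], [], (cx, cy), [])

    def farthest_point(b: int) -> tuple[float, float]:
        near = np.isin(bins, [(b + k) % nbins for k in (-2, -1, 0, 1, 2)])
        sel = np.flatnonzero(near)
        if sel.size == 0:
            return (cx + rmax[b] * math.cos(math.radians(b * bin_w)),
                    cy - rmax[b] * math.sin(math.radians(b * bin_w)))
        best = sel[np.argmax(r[sel])]
        return (float(pts[best, 0]), float(pts[best, 1]))

    tips = [(farthest_point(b), b * bin_w + bin_w / 2) for b in peak_bins]

    if figure == "diamond":
        corners = [p for p, _ in tips]
        classes = ["corner"] * len(corners)
        angles = [a for _, a in tips]
        return pts, CornerSet(corners, classes, (cx, cy), angles)

    # star: the inner vertex between two adjacent tips is recovered as the
    # intersection of line fits to the two straight edges in that wedge
    # (the radial minimum of a straight edge lies mid-edge, not at the
    # vertex, so a profile-valley estimate would bias blunt stars)
    entries: list[tuple[float, tuple[float, float], str]] = []
    m = len(tips)
    tip_margin = 6.0   # degrees excluded around each tip before fitting
    for i in range(m):
        p, a = tips[i]
        entries.append((a, p, "outer"))
        a2 = tips[(i + 1) % m][1]
        span = (a2 - a) % 360.0
        if span < 3 * tip_margin:
            continue
        rel = (theta - a) % 360.0
        half = span / 2.0
        sel1 = (rel >= tip_margin) & (rel <= half)
        sel2 = (rel > half) & (rel <= span - tip_margin)
        if sel1.sum() < 8 or sel2.sum() < 8:
            continue

        def _fit(sel) -> Optional[tuple[np.ndarray, np.ndarray]]:
            sub = pts[sel]
            centered = sub - sub.mean(axis=0)
            _, sv, vt = np.linalg.svd(centered, full_matrices=False)
            return sub.mean(axis=0), vt[0]

        f1 = _fit(sel1)
        f2 = _fit(sel2)
        inner = _line_intersection(f1[0], f1[1], f2[0], f2[1])
        if inner is None:
            # parallel fits: fall back to the profile valley
            between = [(int(a / bin_w) + k) % nbins
                       for k in range(1, int(span / bin_w))]
            cand = [b for b in between if rmax[b] > 0]
            if not cand:
                continue
            vb = min(cand, key=lambda b: rmax[b])
            inner = np.array([cx + rmax[vb] * math.cos(math.radians(vb * bin_w)),
                              cy - rmax[vb] * math.sin(math.radians(vb * bin_w))])
        ia = math.degrees(math.atan2(-(inner[1] - cy), inner[0] - cx)) % 360.0
        entries.append((ia, (float(inner[0]), float(inner[1])), "inner"))

    entries.sort(key=lambda e: e[0])
    angles = [e[0] for e in entries]
    corners = [e[1] for e in entries]
    classes = [e[2] for e in entries]
    return pts, CornerSet(corners, classes, (cx, cy), angles)


# ---------------------------------------------------------------------------
# archetype fitting
# ---------------------------------------------------------------------------

def fit_archetype(corners: CornerSet, figure: str) -> Archetype:
    """Idealized template anchored to the detected corners.

    Outer tips / diamond corners are anchored exactly; star inner vertices
    are snapped to the class-mean radius along their detected direction.
    Translating or uniformly scaling the drawing transforms the archetype
    identically.  Fewer than 3 corners signal a degenerate archetype (shape
    will score 0).
    """
    if len(corners) < 3 or corners.centroid is None:
        return Archetype(figure=figure, vertices=list(corners.corners),
                         degenerate=True)
    cx, cy = corners.centroid

    if figure == "diamond":
        verts = list(corners.corners)
        mid = None
        if len(verts) == 4:
            top = min(verts, key=lambda p: p[1])
            bottom = max(verts, key=lambda p: p[1])
            mid = (top, bottom)
        return Archetype(figure=figure, vertices=verts, midline=mid)

    inner_r = [math.hypot(p[0] - cx, p[1] - cy)
               for p, c in zip(corners.corners, corners.classes)
               if c == "inner"]
    mean_inner = float(np.mean(inner_r)) if inner_r else 0.0
    verts = []
    for p, c, a in zip(corners.corners, corners.classes, corners.angles_deg):
        if c == "outer" or mean_inner == 0.0:
            verts.append(p)
        else:
            rad = math.radians(a)
            verts.append((cx + mean_inner * math.cos(rad),
                          cy - mean_inner * math.sin(rad)))
    return Archetype(figure=figure, vertices=verts)


# ---------------------------------------------------------------------------
# geometric measurements
# ---------------------------------------------------------------------------

def edge_coverage(pts: np.ndarray, p, q,
                  config: PipelineConfig = DEFAULT_CONFIG
                  ) -> tuple[float, float]:
    """(covered fraction, largest uncovered run in px) along edge p→q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    length = float(np.hypot(*(q - p)))
    if length < 1.0 or pts.shape[0] == 0:
        return 0.0, length
    u = (q - p) / length
    n = np.array([-u[1], u[0]])
    rel = pts - p
    t = rel @ u
    d = np.abs(rel @ n)
    pad = 4.0
    sel = (d <= config.copy_corridor_half_px) & (t >= pad) & (t <= length - pad)
    span = length - 2 * pad
    nb = max(int(span), 1)
    covered = np.zeros(nb, dtype=bool)
    if sel.any():
        idx = np.clip(((t[sel] - pad) / span * nb).astype(int), 0, nb - 1)
        covered[idx] = True
    frac = float(covered.mean())
    # largest run of uncovered bins
    max_gap = 0
    run = 0
    for c in covered:
        run = 0 if c else run + 1
        max_gap = max(max_gap, run)
    return frac, float(max_gap)


def edge_present(pts: np.ndarray, p, q,
                 config: PipelineConfig = DEFAULT_CONFIG) -> bool:
    frac, gap = edge_coverage(pts, p, q, config)
    return (frac >= config.copy_edge_min_coverage
            and gap <= config.copy_max_gap_px)


def _fit_edge_direction(pts: np.ndarray, p, q,
                        config: PipelineConfig) -> Optional[np.ndarray]:
    """Principal-axis direction of the ink along edge p→q, oriented p→q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    length = float(np.hypot(*(q - p)))
    if length < 1.0:
        return None
    u = (q - p) / length
    n = np.array([-u[1], u[0]])
    rel = pts - p
    t = rel @ u
    d = np.abs(rel @ n)
    pad = min(10.0, length / 5.0)
    sel = (d <= config.copy_corridor_half_px) & (t >= pad) & (t <= length - pad)
    sub = pts[sel]
    if sub.shape[0] < 8:
        return None
    centered = sub - sub.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction @ u < 0:
        direction = -direction
    return direction


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    c = float(np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                      -1.0, 1.0))
    return math.degrees(math.acos(c))


# ---------------------------------------------------------------------------
# star scoring
# ---------------------------------------------------------------------------

def _radial_deviation(corners: CornerSet, cls: str) -> float:
    cx, cy = corners.centroid
    radii = [math.hypot(p[0] - cx, p[1] - cy) for p in corners.of_class(cls)]
    if not radii:
        return math.inf
    mean = float(np.mean(radii))
    return max(abs(r - mean) for r in radii)


def score_star(pts: np.ndarray, corners: CornerSet, archetype: Archetype,
               criteria: Optional[StarCriteria] = None,
               config: PipelineConfig = DEFAULT_CONFIG) -> CopyScore:
    """NET star criteria: shape (edges + radial consistency), detail
    (exactly 8 corners, gated on shape), arrangement (spans, opposing-tip
    alignment, intermediate spacing, tip angles)."""
    crit = criteria or StarCriteria.from_config(config)
    score = CopyScore()
    if archetype.degenerate or len(corners) < 3:
        score.diagnostics["degenerate"] = True
        return score.finalize()

    verts = archetype.vertices
    edges_ok = all(edge_present(pts, verts[i], verts[(i + 1) % len(verts)],
                                config)
                   for i in range(len(verts)))
    rad_dev = max(_radial_deviation(corners, "outer"),
                  _radial_deviation(corners, "inner"))
    shape = int(edges_ok and rad_dev <= crit.max_radial_deviation)
    score.shape = shape
    score.detail = int(shape and len(corners) == crit.required_corners)
    score.diagnostics.update(edges_ok=edges_ok, radial_deviation=rad_dev,
                             corner_count=len(corners))

    tips = [(p, a) for p, c, a in zip(corners.corners, corners.classes,
                                      corners.angles_deg) if c == "outer"]
    inners = corners.of_class("inner")
    arrangement = 0
    if len(tips) == 4 and len(inners) == 4:
        allc = np.asarray(corners.corners)
        span_x = float(allc[:, 0].max() - allc[:, 0].min())
        span_y = float(allc[:, 1].max() - allc[:, 1].min())
        span_ok = abs(span_x - span_y) <= crit.span_difference_max

        # opposing tip pairs (i, i+2) in angular order; the pair whose
        # connecting line is more horizontal is checked for vertical
        # misalignment and vice versa (axis-aligned — not rotation invariant)
        tp = [np.asarray(p) for p, _ in tips]
        pair_a = (tp[0], tp[2])
        pair_b = (tp[1], tp[3])
        def _mis(pair_h, pair_v):
            return max(abs(pair_h[0][1] - pair_h[1][1]),
                       abs(pair_v[0][0] - pair_v[1][0]))
        da = abs(pair_a[0][0] - pair_a[1][0])
        db = abs(pair_b[0][0] - pair_b[1][0])
        mis = _mis(pair_a, pair_b) if da >= db else _mis(pair_b, pair_a)
        mis_ok = mis <= crit.tip_misalignment_max

        # intermediate (inner) corner spacing uniformity
        inn = [np.asarray(p) for p in inners]
        dists = [float(np.hypot(*(inn[i] - inn[(i + 1) % 4])))
                 for i in range(4)]
        inter_dev = max(abs(d - np.mean(dists)) for d in dists)
        inter_ok = inter_dev <= crit.intermediate_distance_deviation_max

        # tip opening angles from line fits of the two incident edges
        angles = []
        order = [i for i, c in enumerate(corners.classes)]
        ncor = len(corners)
        for i, c in enumerate(corners.classes):
            if c != "outer":
                continue
            tip = np.asarray(corners.corners[i])
            prev = np.asarray(corners.corners[(i - 1) % ncor])
            nxt = np.asarray(corners.corners[(i + 1) % ncor])
            d1 = _fit_edge_direction(pts, tip, prev, config)
            d2 = _fit_edge_direction(pts, tip, nxt, config)
            if d1 is None or d2 is None:
                angles.append(math.nan)
            else:
                angles.append(_angle_between(d1, d2))
        devs = [abs(round(a, 1) - crit.expected_angle) for a in angles]
        angles_valid = all(not math.isnan(a) for a in angles)
        ang_ok = (angles_valid
                  and all(d <= crit.angle_deviation_max for d in devs)
                  and sum(d <= crit.angle_deviation_strict for d in devs)
                  >= crit.min_angles_within_strict)

        arrangement = int(span_ok and mis_ok and inter_ok and ang_ok)
        score.diagnostics.update(
            span_difference=abs(span_x - span_y), tip_misalignment=mis,
            intermediate_deviation=inter_dev, tip_angles=angles)
    score.arrangement = arrangement
    return score.finalize()


# ---------------------------------------------------------------------------
# diamond scoring
# ---------------------------------------------------------------------------

def _midline_present(pts: np.ndarray, top, bottom,
                     config: PipelineConfig) -> bool:
    """Near-vertical stroke spanning the top→bottom corner axis.

    The corridor must be covered with no run of missing ink longer than the
    gap tolerance, and the first/last covered positions must fall within
    the endpoint capture windows — a detached midline counts as absent.
    """
    p = np.asarray(top, dtype=float)
    q = np.asarray(bottom, dtype=float)
    length = float(np.hypot(*(q - p)))
    if length < 10.0 or pts.shape[0] == 0:
        return False
    u = (q - p) / length
    n = np.array([-u[1], u[0]])
    rel = pts - p
    t = rel @ u
    d = np.abs(rel @ n)
    sel = (d <= config.midline_corridor_half_px) & (t >= 0) & (t <= length)
    if not sel.any():
        return False
    nb = max(int(length), 1)
    covered = np.zeros(nb, dtype=bool)
    idx = np.clip((t[sel] / length * nb).astype(int), 0, nb - 1)
    covered[idx] = True
    pos = np.flatnonzero(covered)
    if pos[0] > config.midline_endpoint_tol_px:
        return False
    if (nb - 1 - pos[-1]) > config.midline_endpoint_tol_px:
        return False
    gaps = np.diff(pos)
    if gaps.size and gaps.max() - 1 > config.midline_max_gap_px:
        return False
    return covered.mean() >= config.midline_min_coverage


def score_diamond(pts: np.ndarray, corners: CornerSet, archetype: Archetype,
                  criteria: Optional[DiamondCriteria] = None,
                  config: PipelineConfig = DEFAULT_CONFIG) -> CopyScore:
    """NET diamond criteria: shape (four closed outer edges), detail
    (vertical midline), arrangement (midline-to-edge angles 45° ± 7° with
    at most one violation); plus the hierarchically gated variant."""
    crit = criteria or DiamondCriteria.from_config(config)
    score = CopyScore()
    if archetype.degenerate or len(corners) != 4:
        score.diagnostics["corner_count"] = len(corners)
        return score.finalize()

    verts = archetype.vertices
    edges = [(verts[i], verts[(i + 1) % 4]) for i in range(4)]
    edges_ok = all(edge_present(pts, a, b, config) for a, b in edges)
    score.shape = int(edges_ok)

    top = min(verts, key=lambda p: p[1])
    bottom = max(verts, key=lambda p: p[1])
    midline_ok = _midline_present(pts, top, bottom, config)
    score.detail = int(midline_ok)

    # angles between the vertical (top-bottom) axis and the four outer
    # edges, measured from line fits at the top and bottom corners
    axis = np.asarray(bottom, float) - np.asarray(top, float)
    axis = axis / np.linalg.norm(axis)
    others = [v for v in verts if v is not top and v is not bottom]
    angles = []
    for corner, sign in ((top, 1.0), (bottom, -1.0)):
        for other in others:
            d = _fit_edge_direction(pts, corner, other, config)
            if d is None:
                angles.append(math.nan)
            else:
                angles.append(_angle_between(d, sign * axis))
    if any(math.isnan(a) for a in angles):
        violations = 4
    else:
        # angles are quantized to the measurement's 0.1° resolution so
        # that drawings exactly on the printed ±7° boundary are not
        # tipped over by sub-resolution fit noise
        violations = sum(abs(round(a, 1) - crit.expected_half_angle)
                         > crit.angle_tolerance for a in angles)
    score.arrangement = int(violations <= crit.max_violations_allowed)
    score.diagnostics.update(edges_ok=edges_ok, midline=midline_ok,
                             axis_angles=angles, violations=violations)
    return score.finalize()


# ---------------------------------------------------------------------------
# sheet-level entry point
# ---------------------------------------------------------------------------

def score_copy_sheet(ink: InkMask, template: LayoutTemplate, sv_table,
                     config: PipelineConfig = DEFAULT_CONFIG) -> CopyScore:
    figure = "star" if template.subtest_id == "copy_star" else "diamond"
    pts, corners = extract_drawing(ink, template.drawing_region, figure,
                                   config)
    archetype = fit_archetype(corners, figure)
    if figure == "star":
        score = score_star(pts, corners, archetype, config=config)
    else:
        score = score_diamond(pts, corners, archetype, config=config)
    from .battery import sv_lookup
    score.standard_value = sv_lookup(score.net_sum, sv_table)
    score.diagnostics["archetype"] = archetype
    return score
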