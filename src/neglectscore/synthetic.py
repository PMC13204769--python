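"""Seeded synthetic test sheets with exact ground truth.

Stands in for the copyrighted printed sheets and for clinical scans, which
cannot be shipped: every sheet is a pure function of a
:class:`SyntheticSpec` (layout + response model + corruption + seed), and
the accompanying :class:`GroundTruth` records every stochastic choice the
renderer made, so scoring results can be checked target-by-target.

The response model emulates the lateralized omission pattern that defines
unilateral neglect: the probability of crossing out a target decays from
the right edge of the sheet to the left, with a steepness controlled by a
severity parameter s ∈ [0, 1] (s = 0 reproduces an unimpaired patient who
crosses everything; at s = 1 the leftmost targets are almost always
omitted).  Bisection marks are displaced rightward by a severity-scaled
bias plus Gaussian jitter; copy drawings can carry vertex jitter,
tremor-induced waviness, edge gaps (biased to the left half at higher
severity) and deleted tips.

Randomness is drawn from one seed split into named substreams (responses,
strokes, corruption), so toggling scan corruption never changes the
simulated responses.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image
from scipy import ndimage

from . import _draw
from .config import DEFAULT_CONFIG, PipelineConfig
from .layout import (CANCELLATION_SUBTESTS, LayoutTemplate, SUBTESTS,
                     make_template, render_printed)
from .pipeline import SheetImage


class SpecError(Exception):
    pass


@dataclass
class SyntheticSpec:
    subtest_id: str
    seed: int = 0
    severity: float = 0.0
    layout_seed: int = 0

    # cancellation response model
    crossing_steepness: float = 8.0
    crossing_midpoint: float = 0.35

    # bisection response model
    bisect_bias_frac: float = 0.35       # mean offset at s=1, × half-length
    bisect_offset_sd_px: float = 10.0
    bisect_offsets: Optional[dict] = None  # explicit per-label overrides (px)
    bisect_extra_mark_offset: Optional[float] = None  # second mark (QC tests)

    # copy distortion
    copy_scale: float = 1.0
    copy_center_offset: tuple[float, float] = (0.0, 0.0)
    star_outer_radius: float = 280.0
    star_tip_angle_deg: float = 110.0
    star_n_tips: int = 4
    star_rotation_deg: float = 0.0
    diamond_half_width: float = 240.0
    diamond_angle_deltas: tuple[float, float] = (0.0, 0.0)  # top, bottom
    #: explicit midline-to-edge angles (tl, tr, bl, br); overrides deltas
    diamond_angles: Optional[tuple[float, float, float, float]] = None
    draw_midline: bool = True
    midline_gap_px: float = 0.0          # detach midline from the corners
    vertex_jitter_sd_px: float = 0.0
    tremor_amplitude_px: float = 0.0
    tremor_waves: float = 6.0
    gap_probability: float = 0.0
    gap_width_px: float = 30.0
    left_gap_boost: float = 0.3          # extra gap prob. on left edges × s
    delete_tip: Optional[int] = None     # index of an outer tip to omit

    # stroke quality
    stroke_width: float = 4.0
    stroke_intensity: int = 25

    # scan corruption
    rotation_deg: float = 0.0
    noise_density: float = 0.0
    contrast_factor: float = 1.0         # < 1 fades ink toward white
    render_scale: float = 1.0            # output resolution / canonical

    def __post_init__(self):
        if self.subtest_id not in SUBTESTS:
            raise SpecError(f"unknown subtest {self.subtest_id!r}")
        if not 0.0 <= self.severity <= 1.0:
            raise SpecError("severity must lie in [0, 1]")
        if not 0.0 <= self.gap_probability <= 1.0:
            raise SpecError("gap_probability must lie in [0, 1]")


@dataclass
class GroundTruth:
    subtest_id: str
    seed: int
    crossed: dict = field(default_factory=dict)          # target id → bool
    bisection_offsets: dict = field(default_factory=dict)  # label → px
    copy_geometry: dict = field(default_factory=dict)
    corruption: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------

def _rng(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        [int(seed), zlib.crc32(name.encode())]))


def crossing_probability(u, severity: float, steepness: float = 8.0,
                         midpoint: float = 0.35):
    """P(cross | normalized position u), u = 0 at the leftmost target.

    p = 1 − s · σ(k (m − u)): exactly 1 everywhere at s = 0, nonincreasing
    in severity, nondecreasing from left to right.
    """
    u = np.asarray(u, dtype=float)
    return 1.0 - severity / (1.0 + np.exp(-steepness * (midpoint - u)))


def neglect_response_model(xs, severity: float, seed: int,
                           steepness: float = 8.0,
                           midpoint: float = 0.35) -> np.ndarray:
    """Crossed/omitted flags for targets at x-positions ``xs``."""
    xs = np.asarray(xs, dtype=float)
    span = xs.max() - xs.min()
    u = (xs - xs.min()) / span if span > 0 else np.ones_like(xs)
    p = crossing_probability(u, severity, steepness, midpoint)
    rng = _rng(seed, "responses")
    return rng.random(xs.size) < p


# ---------------------------------------------------------------------------
# patient-ink rendering
# ---------------------------------------------------------------------------

def _tremor_polyline(p, q, rng, amplitude: float, waves: float,
                     n: int = 24) -> list[tuple[float, float]]:
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    t = np.linspace(0.0, 1.0, n)
    base = p[None, :] + t[:, None] * (q - p)[None, :]
    if amplitude > 0:
        d = q - p
        length = np.hypot(*d)
        nvec = np.array([-d[1], d[0]]) / max(length, 1e-9)
        phase = rng.uniform(0, 2 * math.pi)
        off = amplitude * np.sin(2 * math.pi * waves * t + phase)
        off *= np.sin(math.pi * t)        # pinned at the endpoints
        base = base + off[:, None] * nvec[None, :]
    return [tuple(row) for row in base]


def _draw_response_edge(img, p, q, spec: SyntheticSpec, rng_strokes,
                        gap_at: Optional[float] = None) -> None:
    pts = _tremor_polyline(p, q, rng_strokes, spec.tremor_amplitude_px,
                           spec.tremor_waves)
    if gap_at is None:
        _draw.draw_polyline(img, pts, width=spec.stroke_width,
                            intensity=spec.stroke_intensity)
        return
    length = math.hypot(q[0] - p[0], q[1] - p[1])
    half = spec.gap_width_px / 2.0 / max(length, 1e-9)
    t = np.linspace(0.0, 1.0, len(pts))
    seg_a = [pt for pt, ti in zip(pts, t) if ti < gap_at - half]
    seg_b = [pt for pt, ti in zip(pts, t) if ti > gap_at + half]
    for seg in (seg_a, seg_b):
        if len(seg) >= 2:
            _draw.draw_polyline(img, seg, width=spec.stroke_width,
                                intensity=spec.stroke_intensity)


def _render_cancellation(img, template: LayoutTemplate, spec: SyntheticSpec,
                         truth: GroundTruth) -> None:
    scoreable = [t for t in template.targets if not t.excluded]
    xs = np.array([t.x for t in scoreable])
    crossed = neglect_response_model(xs, spec.severity, spec.seed,
                                     spec.crossing_steepness,
                                     spec.crossing_midpoint)
    rng_strokes = _rng(spec.seed, "strokes")
    for t, c in zip(scoreable, crossed):
        truth.crossed[t.id] = bool(c)
        if not c:
            continue
        if t.kind == "line":
            # a crossing stroke is transversal to the printed line
            ang = math.radians(t.angle + 90.0 + rng_strokes.uniform(-25, 25))
        else:
            ang = math.radians(rng_strokes.uniform(30, 60)
                               * rng_strokes.choice([-1.0, 1.0]))
        half = 18.0 if t.kind == "star_small" else 22.0
        jx, jy = rng_strokes.uniform(-3, 3, size=2)
        p = (t.x + jx - half * math.cos(ang), t.y + jy - half * math.sin(ang))
        q = (t.x + jx + half * math.cos(ang), t.y + jy + half * math.sin(ang))
        _draw.draw_segment(img, p, q, width=spec.stroke_width,
                           intensity=spec.stroke_intensity)
    for t in template.targets:
        if t.excluded:
            # demonstration targets come pre-crossed by the examiner
            truth.crossed[t.id] = True
            _draw.draw_segment(img, (t.x - 16, t.y + 12), (t.x + 16, t.y - 12),
                               width=spec.stroke_width,
                               intensity=spec.stroke_intensity)


def _render_bisection(img, template: LayoutTemplate, spec: SyntheticSpec,
                      truth: GroundTruth) -> None:
    rng_resp = _rng(spec.seed, "responses")
    rng_strokes = _rng(spec.seed, "strokes")
    for line in template.bisection_lines:
        half_len = line.length / 2.0
        if spec.bisect_offsets and line.label in spec.bisect_offsets:
            offset = float(spec.bisect_offsets[line.label])
        else:
            mu = spec.severity * spec.bisect_bias_frac * half_len
            offset = float(rng_resp.normal(mu, spec.bisect_offset_sd_px))
            offset = float(np.clip(offset, -0.9 * half_len, 0.9 * half_len))
        truth.bisection_offsets[line.label] = offset
        mid_x, y = line.midpoint
        tilt = rng_strokes.uniform(-5, 5)
        x = mid_x + offset - tilt / 2.0
        _draw.draw_segment(img, (x, y - 35), (x + tilt, y + 35),
                           width=spec.stroke_width,
                           intensity=spec.stroke_intensity)
        if spec.bisect_extra_mark_offset is not None:
            x2 = mid_x + spec.bisect_extra_mark_offset
            _draw.draw_segment(img, (x2, y - 35), (x2, y + 35),
                               width=spec.stroke_width,
                               intensity=spec.stroke_intensity)


def _star_tip_angles(verts: list[tuple[float, float]]) -> list[float]:
    """Opening angle at each outer vertex (outer/inner alternating list)."""
    n = len(verts)
    out = []
    for i in range(0, n, 2):
        tip = np.asarray(verts[i])
        a = np.asarray(verts[(i - 1) % n]) - tip
        b = np.asarray(verts[(i + 1) % n]) - tip
        c = float(np.clip(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)),
                          -1, 1))
        out.append(math.degrees(math.acos(c)))
    return out


def _render_copy(img, template: LayoutTemplate, spec: SyntheticSpec,
                 truth: GroundTruth) -> None:
    rng_resp = _rng(spec.seed, "responses")
    rng_strokes = _rng(spec.seed, "strokes")
    x0, y0, x1, y1 = template.drawing_region
    cx = (x0 + x1) / 2.0 + spec.copy_center_offset[0]
    cy = (y0 + y1) / 2.0 + spec.copy_center_offset[1]

    if template.subtest_id == "copy_star":
        verts = _draw.star_vertices((cx, cy),
                                    spec.star_outer_radius * spec.copy_scale,
                                    spec.star_tip_angle_deg,
                                    spec.star_n_tips, spec.star_rotation_deg)
    elif spec.diamond_angles is not None:
        verts = _draw.diamond_vertices_from_angles(
            (cx, cy), spec.diamond_half_width * spec.copy_scale,
            spec.diamond_angles)
    else:
        verts = _draw.diamond_vertices(
            (cx, cy), spec.diamond_half_width * spec.copy_scale,
            *spec.diamond_angle_deltas)
    if spec.vertex_jitter_sd_px > 0:
        verts = [(vx + rng_resp.normal(0, spec.vertex_jitter_sd_px),
                  vy + rng_resp.normal(0, spec.vertex_jitter_sd_px))
                 for vx, vy in verts]

    n = len(verts)
    edges = [(i, (i + 1) % n) for i in range(n)]
    omitted: list[int] = []
    if spec.delete_tip is not None and template.subtest_id == "copy_star":
        tip_vertex = 2 * spec.delete_tip
        omitted = [e for e, (i, j) in enumerate(edges)
                   if i == tip_vertex or j == tip_vertex]

    gaps: dict[int, float] = {}
    for e, (i, j) in enumerate(edges):
        if e in omitted:
            continue
        mid_x = (verts[i][0] + verts[j][0]) / 2.0
        p_gap = spec.gap_probability
        if mid_x < cx:
            p_gap = min(p_gap + spec.severity * spec.left_gap_boost, 1.0)
        if p_gap > 0 and rng_resp.random() < p_gap:
            gaps[e] = float(rng_resp.uniform(0.35, 0.65))

    for e, (i, j) in enumerate(edges):
        if e in omitted:
            continue
        _draw_response_edge(img, verts[i], verts[j], spec, rng_strokes,
                            gap_at=gaps.get(e))

    midline_drawn = False
    if template.subtest_id == "copy_diamond" and spec.draw_midline:
        top, bottom = verts[0], verts[2]
        g = spec.midline_gap_px
        _draw_response_edge(img, (top[0], top[1] + g),
                            (bottom[0], bottom[1] - g), spec, rng_strokes)
        midline_drawn = True

    geom = {
        "vertices": [list(v) for v in verts],
        "omitted_edges": omitted,
        "gapped_edges": {str(e): [g, spec.gap_width_px]
                         for e, g in gaps.items()},
        "midline_drawn": midline_drawn,
        "midline_gap_px": spec.midline_gap_px,
    }
    if template.subtest_id == "copy_star":
        geom["tip_angles"] = _star_tip_angles(verts) if not omitted else []
    elif spec.diamond_angles is not None:
        geom["axis_angles"] = list(spec.diamond_angles)
    else:
        geom["axis_angles"] = [45.0 + spec.diamond_angle_deltas[0]] * 2 + \
                              [45.0 + spec.diamond_angle_deltas[1]] * 2
    truth.copy_geometry = geom


# ---------------------------------------------------------------------------
# corruption and assembly
# ---------------------------------------------------------------------------

def _apply_corruption(img: np.ndarray, spec: SyntheticSpec,
                      truth: GroundTruth) -> np.ndarray:
    rng = _rng(spec.seed, "corruption")
    if spec.rotation_deg:
        arr = ndimage.rotate(img.astype(np.float32), spec.rotation_deg,
                             reshape=False, order=1, mode="constant",
                             cval=255.0)
        img = np.clip(arr, 0, 255).astype(np.uint8)
    n_specks = 0
    if spec.noise_density > 0:
        n_specks = int(round(spec.noise_density * img.size))
        ys = rng.integers(0, img.shape[0], n_specks)
        xs = rng.integers(0, img.shape[1], n_specks)
        img = img.copy()
        img[ys, xs] = 0
    truth.corruption = {"rotation_deg": spec.rotation_deg,
                        "noise_density": spec.noise_density,
                        "n_specks": n_specks,
                        "contrast_factor": spec.contrast_factor}
    return img


def render_response_layer(spec: SyntheticSpec,
                          config: PipelineConfig = DEFAULT_CONFIG,
                          template: Optional[LayoutTemplate] = None,
                          truth: Optional[GroundTruth] = None) -> np.ndarray:
    """Patient ink alone on a white page (pre-corruption).

    This is exactly the stroke raster composed into :func:`render_sheet`
    for the same spec, so it can serve as a pixel-level oracle for ink
    isolation.  A faint writing tool (``contrast_factor`` < 1) fades only
    this layer, never the printed template.
    """
    if template is None:
        template = make_template(spec.subtest_id, config, spec.layout_seed)
    if truth is None:
        truth = GroundTruth(subtest_id=spec.subtest_id, seed=spec.seed)
    layer = _draw.blank_page(config.canonical_width, config.canonical_height)
    if spec.subtest_id in CANCELLATION_SUBTESTS:
        _render_cancellation(layer, template, spec, truth)
    elif spec.subtest_id == "line_bisection":
        _render_bisection(layer, template, spec, truth)
    else:
        _render_copy(layer, template, spec, truth)
    if spec.contrast_factor != 1.0:
        arr = 255.0 - spec.contrast_factor * (255.0 - layer.astype(np.float64))
        layer = np.clip(arr, 0, 255).astype(np.uint8)
    return layer


def render_sheet(spec: SyntheticSpec,
                 config: PipelineConfig = DEFAULT_CONFIG,
                 template: Optional[LayoutTemplate] = None
                 ) -> tuple[SheetImage, GroundTruth]:
    """Deterministic render of one completed test sheet plus ground truth."""
    if template is None:
        template = make_template(spec.subtest_id, config, spec.layout_seed)
    if template.drawing_region is not None:
        x0, y0, x1, y1 = template.drawing_region
        if not (0 <= x0 < x1 <= config.canonical_width
                and 0 <= y0 < y1 <= config.canonical_height):
            raise SpecError("drawing region exceeds the page bounds")
    truth = GroundTruth(subtest_id=spec.subtest_id, seed=spec.seed)
    ink_layer = render_response_layer(spec, config, template, truth)
    img = np.minimum(render_printed(template, config), ink_layer)

    img = _apply_corruption(img, spec, truth)

    if spec.render_scale != 1.0:
        w = int(round(img.shape[1] * spec.render_scale))
        h = int(round(img.shape[0] * spec.render_scale))
        pil = Image.fromarray(img).resize((w, h), Image.LANCZOS)
        img = np.asarray(pil, dtype=np.uint8)

    sheet = SheetImage(pixels=img, canonical_scale=config.mm_per_px,
                       source_path=f"<synthetic:{spec.subtest_id}:{spec.seed}>")
    return sheet, truth


# ---------------------------------------------------------------------------
# batch emission (PNG + JSON sidecars + templates + manifest)
# ---------------------------------------------------------------------------

def write_sheet(outdir: str | Path, name: str, sheet: SheetImage,
                truth: GroundTruth) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    png = outdir / f"{name}.png"
    Image.fromarray(sheet.pixels).save(png)
    (outdir / f"{name}.truth.json").write_text(truth.to_json())
    return png


def make_batch(outdir: str | Path, n_patients: int, seed: int,
               config: PipelineConfig = DEFAULT_CONFIG,
               subtests=SUBTESTS, severities=None) -> Path:
    """Emit a scored-batch fixture: one sheet per patient × subtest, the
    matching layout templates, ground-truth sidecars and a manifest CSV.

    Returns the manifest path.  Per-patient severities default to an even
    spread over [0, 0.9].
    """
    outdir = Path(outdir)
    (outdir / "templates").mkdir(parents=True, exist_ok=True)
    for s in subtests:
        make_template(s, config).save(outdir / "templates" / f"{s}.yaml")
    if severities is None:
        severities = (np.linspace(0.0, 0.9, n_patients) if n_patients > 1
                      else [0.0])
    rows = ["patient_id,subtest,file"]
    for i in range(n_patients):
        pid = f"P{i:03d}"
        for j, subtest in enumerate(subtests):
            spec = SyntheticSpec(subtest_id=subtest,
                                 seed=seed + 1000 * i + j,
                                 severity=float(severities[i]))
            sheet, truth = render_sheet(spec, config)
            write_sheet(outdir, f"{pid}_{subtest}", sheet, truth)
            rows.append(f"{pid},{subtest},{pid}_{subtest}.png")
    manifest = outdir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
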