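"""Line-bisection scoring.

Each of the three printed horizontal lines (top/middle/bottom) is searched
for the patient's midpoint mark inside a narrow band around the line.  The
mark position is the ink-density-weighted centroid of the crossing cluster;
separated clusters mean the patient marked multiple midpoints, which the
scan-selection rules treat as unscorable.  The signed deviation from the
true midpoint is mapped through nested zone bands — expressed as fractions
of the half-line length — to 3/2/1/0 points plus an L/R direction flag.
Band boundaries are closed on the inner side (a deviation exactly on a
boundary earns the higher score), a documented dialect choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .layout import BisectionLineSpec, LayoutTemplate
from .pipeline import InkMask


class NoMarkError(Exception):
    """No candidate bisection mark near the line."""


class MultipleMarksError(Exception):
    """Two or more separated candidate marks on one line."""

    def __init__(self, label: str, positions):
        self.label = label
        self.positions = list(positions)
        super().__init__(f"line {label}: {len(self.positions)} separated "
                         f"marks at x={self.positions}")


@dataclass
class BisectionLineResult:
    label: str                       # 'T', 'M' or 'B'
    mark_x: Optional[float]
    deviation: Optional[float]       # signed px, negative = left of centre
    points: Optional[int]            # 3 / 2 / 1 / 0, None when unresolved
    direction: str                   # 'L', 'R', 'center' or '' when unresolved
    flag: Optional[str] = None       # 'no_mark' | 'multiple_marks'

    def serialize(self) -> str:
        """Points+direction cell, e.g. ``"2L"``; centre has no letter."""
        if self.points is None:
            return ""
        suffix = {"L": "L", "R": "R", "center": ""}[self.direction]
        return f"{self.points}{suffix}"


@dataclass
class BisectionResult:
    lines: list[BisectionLineResult]
    total: Optional[int]
    standard_value: Optional[float]
    needs_review: bool = False

    def as_tuple(self) -> tuple:
        """(LineB_T, LineB_M, LineB_B, LineB, LineB_SV)."""
        by_label = {l.label: l for l in self.lines}
        return (by_label["T"].serialize(), by_label["M"].serialize(),
                by_label["B"].serialize(), self.total, self.standard_value)


# ---------------------------------------------------------------------------
# mark detection
# ---------------------------------------------------------------------------

def find_mark_clusters(ink: InkMask, line: BisectionLineSpec,
                       config: PipelineConfig = DEFAULT_CONFIG
                       ) -> list[tuple[float, int]]:
    """Ink clusters crossing the line's band → [(centroid x, px count)].

    Clusters are x-intervals of patient ink within the band, merged when
    separated by less than ``bisect_cluster_gap_px``.
    """
    h, w = ink.mask.shape
    y = line.midpoint[1]
    band = ink.mask[max(int(y - config.bisect_band_half_px), 0):
                    min(int(y + config.bisect_band_half_px) + 1, h)]
    pad = 30
    xa = max(int(line.x_left - pad), 0)
    xb = min(int(line.x_right + pad) + 1, w)
    counts = band[:, xa:xb].sum(axis=0)
    xs = np.flatnonzero(counts)
    if xs.size == 0:
        return []
    clusters = []
    start = prev = xs[0]
    for x in xs[1:]:
        if x - prev > config.bisect_cluster_gap_px:
            clusters.append((start, prev))
            start = x
        prev = x
    clusters.append((start, prev))
    out = []
    for a, b in clusters:
        seg = counts[a:b + 1]
        pos = np.arange(a, b + 1)
        centroid = float((pos * seg).sum() / seg.sum()) + xa
        out.append((centroid, int(seg.sum())))
    return out


def detect_bisection_mark(ink: InkMask, line: BisectionLineSpec,
                          config: PipelineConfig = DEFAULT_CONFIG) -> float:
    """x-coordinate of the single bisection mark on ``line``.

    Raises :class:`NoMarkError` when the band holds no ink and
    :class:`MultipleMarksError` when separated clusters are present.
    """
    clusters = find_mark_clusters(ink, line, config)
    if not clusters:
        raise NoMarkError(f"no ink near line {line.label}")
    if len(clusters) >= 2:
        raise MultipleMarksError(line.label, [c[0] for c in clusters])
    return clusters[0][0]


# ---------------------------------------------------------------------------
# zone scoring
# ---------------------------------------------------------------------------

def zone_points(deviation: float, half_length: float,
                fractions=DEFAULT_CONFIG.bisect_zone_fractions) -> int:
    """Band lookup: 3/2/1 points inside the nested bands, 0 outside."""
    d = abs(deviation)
    for pts, frac in zip((3, 2, 1), fractions):
        if d <= frac * half_length:
            return pts
    return 0


def score_line(mark_x: float, line: BisectionLineSpec,
               config: PipelineConfig = DEFAULT_CONFIG) -> BisectionLineResult:
    mid_x = line.midpoint[0]
    deviation = mark_x - mid_x
    pts = zone_points(deviation, line.length / 2.0,
                      config.bisect_zone_fractions)
    if deviation < 0:
        direction = "L"
    elif deviation > 0:
        direction = "R"
    else:
        direction = "center"
    return BisectionLineResult(label=line.label, mark_x=mark_x,
                               deviation=deviation, points=pts,
                               direction=direction)


def score_bisection(line_results: list[BisectionLineResult],
                    sv_table) -> BisectionResult:
    """Sum the three line scores and convert to the NET standard value.

    Unresolved lines (no mark / multiple marks) propagate: the partial
    result is marked for manual review and the total left empty.
    """
    unresolved = [l for l in line_results if l.points is None]
    if unresolved:
        return BisectionResult(lines=line_results, total=None,
                               standard_value=None, needs_review=True)
    total = sum(l.points for l in line_results)
    from .battery import sv_lookup
    return BisectionResult(lines=line_results, total=total,
                           standard_value=sv_lookup(total, sv_table))


def score_sheet(ink: InkMask, template: LayoutTemplate, sv_table,
                config: PipelineConfig = DEFAULT_CONFIG) -> BisectionResult:
    results = []
    for line in template.bisection_lines:
        try:
            x = detect_bisection_mark(ink, line, config)
        except NoMarkError:
            results.append(BisectionLineResult(
                label=line.label, mark_x=None, deviation=None, points=None,
                direction="", flag="no_mark"))
        except MultipleMarksError:
            results.append(BisectionLineResult(
                label=line.label, mark_x=None, deviation=None, points=None,
                direction="", flag="multiple_marks"))
        else:
            results.append(score_line(x, line, config))
    return score_bisection(results, sv_table)
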