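"""Cancellation-task scoring (line crossing, letter and star cancellation).

A printed target counts as crossed out when the fraction of patient ink in
an axis-aligned window around its centre reaches a configured threshold.
Windowed coverage makes the decision monotone in ink (adding strokes can
only switch targets from uncrossed to crossed) and insensitive to zigzag or
repeated crossings within one target.  Targets in the middle column and
targets flagged as excluded (e.g. the examiner's demonstration stars at the
sheet centre) never contribute to the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .layout import LayoutTemplate
from .pipeline import InkMask


class ScoringError(Exception):
    """Internal-consistency failure between records and template."""


@dataclass
class TargetRecord:
    target_id: str
    x: float
    y: float
    side: str                    # 'L', 'M' or 'R'
    excluded: bool
    crossed: bool
    ink_score: float             # ink fraction of the detection window


@dataclass
class CancellationResult:
    subtest_id: str
    left_count: int
    right_count: int
    total: int
    standard_value: float
    records: list[TargetRecord] = field(default_factory=list)

    def as_tuple(self) -> tuple:
        """(LS, RS, total, SV) — the per-subtest output tuple."""
        return (self.left_count, self.right_count, self.total,
                self.standard_value)


def target_ink_fraction(ink: InkMask, x: float, y: float,
                        half: int) -> float:
    h, w = ink.mask.shape
    ya, yb = max(int(round(y)) - half, 0), min(int(round(y)) + half + 1, h)
    xa, xb = max(int(round(x)) - half, 0), min(int(round(x)) + half + 1, w)
    win = ink.mask[ya:yb, xa:xb]
    return float(win.mean()) if win.size else 0.0


def detect_crossings(ink: InkMask, template: LayoutTemplate,
                     config: PipelineConfig = DEFAULT_CONFIG
                     ) -> list[TargetRecord]:
    """Decide, for every template target, whether the patient crossed it."""
    half = config.cancel_window_half_px
    records = []
    for t in template.targets:
        frac = target_ink_fraction(ink, t.x, t.y, half)
        records.append(TargetRecord(
            target_id=t.id, x=t.x, y=t.y, side=t.side, excluded=t.excluded,
            crossed=frac >= config.cancel_ink_fraction, ink_score=frac))
    return records


def score_cancellation(records: list[TargetRecord], subtest_id: str,
                       sv_table) -> CancellationResult:
    """Left/right/total counts over scoreable targets plus the NET standard
    value.  Middle-column and excluded targets are ignored."""
    left = sum(1 for r in records
               if r.crossed and not r.excluded and r.side == "L")
    right = sum(1 for r in records
                if r.crossed and not r.excluded and r.side == "R")
    total = left + right
    from .battery import sv_lookup
    sv = sv_lookup(total, sv_table)
    return CancellationResult(subtest_id=subtest_id, left_count=left,
                              right_count=right, total=total,
                              standard_value=sv, records=records)


def score_sheet(ink: InkMask, template: LayoutTemplate, sv_table,
                config: PipelineConfig = DEFAULT_CONFIG) -> CancellationResult:
    records = detect_crossings(ink, template, config)
    expected = {t.id for t in template.targets}
    got = {r.target_id for r in records}
    if expected != got:
        raise ScoringError(f"records do not cover the template: "
                           f"missing {sorted(expected - got)}")
    return score_cancellation(records, template.subtest_id, sv_table)
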