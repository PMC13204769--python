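"""Battery-level scoring arithmetic.

Implements the NET standard-value (SV) conversion (raw subtest scores to a
0–10 scale in 0.5 steps), the subset weighting used to preserve the BIT-c's
incidental weighting when only part of the battery is administered
(subset weight = subtest maximum / sum of used maxima × 100), the weighted
BIT-c total with its proportionally scaled neglect cut-off (≤ 129 of 146
points in the full battery), and the NET severity bands (≤ 72 / 135 / 166
of 170 full-battery points, proportionally rescaled to the subset's SV
maximum).  All reported totals are rounded half-up at 2 decimals.

Only the letter-cancellation SV table is public (0–1 → 0, 2–3 → 0.5, … in
0.5 steps up to 10 for all 40 targets).  For the other subtests the default
tables use a proportional mapping — raw / raw_max × 10, rounded down to the
nearest 0.5 — shipped as editable config; owners of the test manuals should
substitute the official tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence


class BatteryInputError(Exception):
    pass


def round_half_up(value: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# standard values
# ---------------------------------------------------------------------------

@dataclass
class SVTable:
    """Ordered raw-score ranges → standard values in {0, 0.5, …, 10}."""
    subtest_id: str
    breakpoints: list[tuple[int, int, float]]   # (raw_lo, raw_hi, sv)

    def __post_init__(self):
        prev_hi = -1
        prev_sv = -1.0
        for lo, hi, sv in self.breakpoints:
            if lo != prev_hi + 1:
                raise ValueError("SV ranges must partition [0, raw_max]")
            if hi < lo or sv < prev_sv:
                raise ValueError("SV table must be nondecreasing")
            if (sv * 2) % 1 != 0 or not 0 <= sv <= 10:
                raise ValueError("SVs must lie in {0, 0.5, …, 10}")
            prev_hi, prev_sv = hi, sv
        if self.breakpoints[-1][2] != 10.0:
            raise ValueError("the maximum raw score must map to SV 10")

    @property
    def raw_max(self) -> int:
        return self.breakpoints[-1][1]


def letter_sv_table() -> SVTable:
    """The published letter-cancellation conversion: 0–1 → 0, 2–3 → 0.5,
    rising in 0.5 steps to 10 for all 40 targets."""
    rows = [(2 * k, 2 * k + 1, k * 0.5) for k in range(20)]
    rows.append((40, 40, 10.0))
    return SVTable("letter_cancellation", rows)


def proportional_sv_table(subtest_id: str, raw_max: int) -> SVTable:
    """Default stand-in table: raw / raw_max × 10 floored to 0.5 steps."""
    rows = []
    start = 0
    prev_sv = 0.0
    for raw in range(0, raw_max + 1):
        sv = min(int(raw / raw_max * 20) / 2.0, 10.0)
        if raw == raw_max:
            sv = 10.0
        if raw > 0 and sv != prev_sv:
            rows.append((start, raw - 1, prev_sv))
            start = raw
        prev_sv = sv
    rows.append((start, raw_max, prev_sv))
    return SVTable(subtest_id, rows)


def default_sv_tables(raw_maxima: dict[str, int]) -> dict[str, SVTable]:
    tables = {}
    for subtest, raw_max in raw_maxima.items():
        if subtest == "letter_cancellation" and raw_max == 40:
            tables[subtest] = letter_sv_table()
        else:
            tables[subtest] = proportional_sv_table(subtest, raw_max)
    return tables


def sv_lookup(raw: int, table: SVTable) -> float:
    if not 0 <= raw <= table.raw_max:
        raise BatteryInputError(
            f"raw score {raw} outside [0, {table.raw_max}] "
            f"for {table.subtest_id}")
    for lo, hi, sv in table.breakpoints:
        if lo <= raw <= hi:
            return sv
    raise AssertionError("unreachable: table partitions the range")


# ---------------------------------------------------------------------------
# subset weighting and the weighted BIT-c total
# ---------------------------------------------------------------------------

@dataclass
class WeightConfig:
    subtests: list[str]
    maxima: list[float]
    fractions: list[float] = field(init=False)

    def __post_init__(self):
        if not self.maxima:
            raise BatteryInputError("empty subtest list")
        if any(m <= 0 for m in self.maxima):
            raise BatteryInputError("subtest maxima must be positive")
        total = sum(self.maxima)
        self.fractions = [m / total for m in self.maxima]

    @property
    def percentages(self) -> list[float]:
        return [round_half_up(100.0 * f) for f in self.fractions]

    @property
    def max_weighted_total(self) -> float:
        return sum(m * f for m, f in zip(self.maxima, self.fractions))


def subset_weights(maxima: Sequence[float],
                   subtests: Optional[Sequence[str]] = None) -> WeightConfig:
    """Weight fractions max_s / Σ max for the administered subtests."""
    maxima = list(maxima)
    names = list(subtests) if subtests else [f"s{i}" for i in range(len(maxima))]
    return WeightConfig(subtests=names, maxima=maxima)


def weighted_total(raw_scores: Sequence[Optional[float]],
                   weights: WeightConfig) -> tuple[Optional[float], bool]:
    """Σ raw_s × weight_fraction_s at 2 decimals.

    Returns (total, partial): a missing subtest yields a partial total
    computed over the available scores, flagged ``partial=True``.
    """
    if len(raw_scores) != len(weights.fractions):
        raise BatteryInputError("one raw score per weighted subtest required")
    acc = 0.0
    partial = False
    seen = False
    for raw, frac in zip(raw_scores, weights.fractions):
        if raw is None:
            partial = True
            continue
        acc += raw * frac
        seen = True
    if not seen:
        return None, True
    return round_half_up(acc), partial


# ---------------------------------------------------------------------------
# diagnostic cut-offs
# ---------------------------------------------------------------------------

@dataclass
class DiagnosisConfig:
    bit_full_cutoff: float = 129.0
    bit_full_max: float = 146.0
    net_full_cutoffs: tuple[float, float, float] = (72.0, 135.0, 166.0)
    net_full_max: float = 170.0

    def __post_init__(self):
        c = self.net_full_cutoffs
        if not (c[0] < c[1] < c[2] < self.net_full_max):
            raise ValueError("NET cutoffs must increase below the maximum")
        if not self.bit_full_cutoff < self.bit_full_max:
            raise ValueError("BIT cutoff must lie below the maximum")


DEFAULT_DIAGNOSIS = DiagnosisConfig()


def bit_cutoff(subset_max: float,
               config: DiagnosisConfig = DEFAULT_DIAGNOSIS) -> float:
    """Neglect cut-off scaled to the administered subset's weighted maximum."""
    return round_half_up(subset_max * config.bit_full_cutoff
                         / config.bit_full_max)


def bit_diagnosis(total: float, subset_max: float,
                  config: DiagnosisConfig = DEFAULT_DIAGNOSIS) -> str:
    """'N+' (neglect) when the weighted total falls at or below the scaled
    cut-off, else 'N-'."""
    return "N+" if total <= bit_cutoff(subset_max, config) else "N-"


def net_severity_bands(subset_sv_max: float,
                       config: DiagnosisConfig = DEFAULT_DIAGNOSIS
                       ) -> tuple[float, float, float]:
    return tuple(round_half_up(c / config.net_full_max * subset_sv_max)
                 for c in config.net_full_cutoffs)


def net_severity(sv_total: float, subset_sv_max: float,
                 config: DiagnosisConfig = DEFAULT_DIAGNOSIS) -> str:
    """Severity category from the proportionally rescaled NET bands."""
    b1, b2, b3 = net_severity_bands(subset_sv_max, config)
    if sv_total <= b1:
        return "severe"
    if sv_total <= b2:
        return "strong"
    if sv_total <= b3:
        return "mild"
    return "none"


# ---------------------------------------------------------------------------
# lateralized omission index
# ---------------------------------------------------------------------------

def laterality_index(left_count: int, right_count: int) -> Optional[float]:
    """(R − L) / (R + L) in [−1, 1]; positive means rightward bias, i.e.
    left-side omissions.  Undefined (None) when both counts are zero."""
    if left_count < 0 or right_count < 0:
        raise BatteryInputError("counts must be nonnegative")
    total = left_count + right_count
    if total == 0:
        return None
    return (right_count - left_count) / total
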