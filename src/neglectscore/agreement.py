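"""Agreement and diagnostic-concordance statistics.

Implements, from their defining formulas, the statistics used to compare an
automated scorer against a reference rating (or two human raters):
Krippendorff's alpha (coincidence-matrix form, nominal/ordinal/interval
distances, missing data allowed), weighted Cohen's kappa (linear default,
quadratic optional), the two-way absolute-agreement single-measure
intraclass correlation ICC(A,1) with its F-based confidence interval
(McGraw–Wong convention), tie-corrected Kendall tau-b, simple concordance
summaries (exact agreement, within ±1, mean absolute difference), and the
2×2 diagnostic table (sensitivity / specificity / accuracy, rank-based AUC
when continuous scores are available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class RatingMatrix:
    """units × raters grid of scores; NaN marks a missing rating."""
    values: np.ndarray
    level: str = "interval"          # 'nominal' | 'ordinal' | 'interval'

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 2:
            raise ValueError("need a units × raters matrix with ≥ 2 raters")
        pairable = (~np.isnan(self.values)).sum(axis=1) >= 2
        if not pairable.any():
            raise ValueError("need at least one unit with ≥ 2 ratings")
        if self.level not in ("nominal", "ordinal", "interval"):
            raise ValueError(f"unknown scale level {self.level!r}")


@dataclass
class ConcordanceResult:
    n: int
    exact_agreement_pct: float
    within_one_pct: float
    mean_absolute_difference: float
    icc: Optional[float] = None
    icc_ci: Optional[tuple[float, float]] = None
    weighted_kappa: Optional[float] = None
    kendall_tau: Optional[float] = None
    accuracy_pct: Optional[float] = None
    sensitivity_pct: Optional[float] = None
    specificity_pct: Optional[float] = None
    auc: Optional[float] = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.icc_ci is not None:
            d["icc_ci"] = list(self.icc_ci)
        return d


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------

def _delta_matrix(domain: np.ndarray, counts: np.ndarray, level: str
                  ) -> np.ndarray:
    k = domain.size
    delta = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            if level == "nominal":
                delta[i, j] = 1.0
            elif level == "interval":
                delta[i, j] = (domain[i] - domain[j]) ** 2
            else:  # ordinal: squared sum of in-between coincidence margins
                lo, hi = min(i, j), max(i, j)
                s = counts[lo:hi + 1].sum() - (counts[lo] + counts[hi]) / 2.0
                delta[i, j] = s ** 2
    return delta


def krippendorff_alpha(matrix: RatingMatrix) -> float:
    """alpha = 1 − Do/De via the coincidence matrix.

    Perfect agreement with zero expected disagreement returns 1.0 by
    convention (with a warning).
    """
    vals = matrix.values
    domain = np.unique(vals[~np.isnan(vals)])
    idx = {v: i for i, v in enumerate(domain)}
    k = domain.size
    coincidence = np.zeros((k, k))
    for unit in vals:
        present = unit[~np.isnan(unit)]
        m = present.size
        if m < 2:
            continue
        for a in range(m):
            for b in range(m):
                if a != b:
                    coincidence[idx[present[a]], idx[present[b]]] += 1.0 / (m - 1)
    n_total = coincidence.sum()
    counts = coincidence.sum(axis=0)
    delta = _delta_matrix(domain, counts, matrix.level)
    d_obs = (coincidence * delta).sum()
    expected = np.outer(counts, counts) / (n_total - 1.0)
    d_exp = (expected * delta).sum()
    if d_exp == 0.0:
        warnings.warn("zero expected disagreement; alpha = 1 by convention")
        return 1.0
    return float(1.0 - d_obs / d_exp)


# ---------------------------------------------------------------------------
# weighted Cohen's kappa
# ---------------------------------------------------------------------------

def weighted_kappa(a: Sequence[float], b: Sequence[float],
                   weights: str = "linear") -> float:
    """1 − Σw·O / Σw·E with marginal-product expectation.

    Degenerate marginals (a single category, perfectly agreed) return 1.0
    with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("need equal-length paired vectors")
    cats = np.unique(np.concatenate([a, b]))
    k = cats.size
    if k == 1:
        warnings.warn("single rating category; kappa = 1 by convention")
        return 1.0
    idx = {v: i for i, v in enumerate(cats)}
    obs = np.zeros((k, k))
    for x, y in zip(a, b):
        obs[idx[x], idx[y]] += 1.0
    n = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
    if weights == "linear":
        w = np.abs(ii - jj) / (k - 1)
    elif weights == "quadratic":
        w = ((ii - jj) / (k - 1)) ** 2
    else:
        raise ValueError("weights must be 'linear' or 'quadratic'")
    denom = (w * exp).sum()
    if denom == 0.0:
        warnings.warn("degenerate marginals; kappa = 1 by convention")
        return 1.0
    return float(1.0 - (w * obs).sum() / denom)


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------

def icc_a1(a: Sequence[float], b: Sequence[float], alpha: float = 0.05
           ) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Two-way absolute-agreement single-measure ICC with F-based CI.

    Mean-square decomposition of the n×2 two-way layout; the confidence
    interval follows the McGraw–Wong convention for ICC(A,1).  Returns
    (None, None, None) when the total variance is zero.
    """
    y = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = y.shape
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    grand = y.mean()
    if np.allclose(y, grand):
        return None, None, None
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = y - row_means[:, None] - col_means[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))

    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # Satterthwaite-style F bounds
    aa = k * icc / (n * (1 - icc)) if icc < 1 else math.inf
    bb = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else math.inf
    if math.isinf(aa):
        return float(icc), 1.0, 1.0
    v_num = (aa * msc + bb * mse) ** 2
    v_den = (aa * msc) ** 2 / (k - 1) + (bb * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den if v_den > 0 else 1.0
    f_obs = msr / mse if mse > 0 else math.inf
    fl = stats.f.ppf(1 - alpha / 2, n - 1, v)
    fu = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = (n * (msr - fl * mse)
          / (fl * (k * msc + (k * n - k - n) * mse) + n * msr))
    hi = (n * (fu * msr - mse)
          / (k * msc + (k * n - k - n) * mse + n * fu * msr))
    return float(icc), float(lo), float(hi)


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------

def kendall_tau_b(a: Sequence[float], b: Sequence[float]) -> Optional[float]:
    """Tie-corrected Kendall rank correlation (scores are heavily tied)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    conc = disc = ties_a = ties_b = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            da = a[i] - a[j]
            db = b[i] - b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((conc + disc + ties_a) * (conc + disc + ties_b))
    if denom == 0:
        return None
    return float((conc - disc) / denom)


# ---------------------------------------------------------------------------
# diagnostic concordance
# ---------------------------------------------------------------------------

def diagnostic_concordance(reference: Sequence[str],
                           predicted: Sequence[str],
                           positive: str = "N+",
                           scores: Optional[Sequence[float]] = None) -> dict:
    """Accuracy / sensitivity / specificity from paired diagnosis labels.

    Sensitivity is recall of the positive (neglect) class.  When continuous
    ``scores`` accompany the reference labels, AUC is computed from the
    Mann-Whitney rank statistic (lower score = more impaired = positive).
    A class absent from the reference leaves the affected metric None.
    """
    ref = np.asarray(reference)
    pred = np.asarray(predicted)
    if ref.shape != pred.shape:
        raise ValueError("paired label vectors required")
    pos = ref == positive
    neg = ~pos
    tp = int((pos & (pred == positive)).sum())
    fn = int(pos.sum()) - tp
    tn = int((neg & (pred != positive)).sum())
    fp = int(neg.sum()) - tn
    out = {
        "tp": tp, "fn": fn, "fp": fp, "tn": tn,
        "accuracy_pct": 100.0 * (tp + tn) / ref.size if ref.size else None,
        "sensitivity_pct": 100.0 * tp / (tp + fn) if (tp + fn) else None,
        "specificity_pct": 100.0 * tn / (tn + fp) if (tn + fp) else None,
        "auc": None,
    }
    if scores is not None and (tp + fn) and (tn + fp):
        s = np.asarray(scores, dtype=float)
        ranks = stats.rankdata(-s)       # lower score ranks higher (impaired)
        r_pos = ranks[pos].sum()
        n_pos, n_neg = int(pos.sum()), int(neg.sum())
        out["auc"] = float((r_pos - n_pos * (n_pos + 1) / 2)
                           / (n_pos * n_neg))
    return out


# ---------------------------------------------------------------------------
# vector-level concordance summary
# ---------------------------------------------------------------------------

def concordance(reference: Sequence[float], predicted: Sequence[float],
                kappa_weights: str = "linear") -> ConcordanceResult:
    """Full agreement panel for two paired score vectors."""
    a = np.asarray(reference, dtype=float)
    b = np.asarray(predicted, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = a.size
    if n == 0:
        raise ValueError("no paired non-missing scores")
    diff = np.abs(a - b)
    res = ConcordanceResult(
        n=n,
        exact_agreement_pct=100.0 * float((diff == 0).mean()),
        within_one_pct=100.0 * float((diff <= 1).mean()),
        mean_absolute_difference=float(diff.mean()),
    )
    if n >= 3:
        icc, lo, hi = icc_a1(a, b)
        res.icc = icc
        res.icc_ci = (lo, hi) if icc is not None else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res.weighted_kappa = weighted_kappa(a, b, kappa_weights)
    res.kendall_tau = kendall_tau_b(a, b)
    return res
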