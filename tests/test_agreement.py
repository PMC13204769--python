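"""Agreement statistics against independent brute-force / library oracles."""

import warnings

import numpy as np
import pytest

from neglectscore import agreement


# ---------------------------------------------------------------------------
# independent oracles (deliberately different formulations)
# ---------------------------------------------------------------------------

def alpha_bruteforce(values: np.ndarray, level: str) -> float:
    """Krippendorff's alpha by explicit enumeration of pairable values.

    Observed disagreement: average metric distance over all ordered pairs
    of values within each unit, weighted by 1/(m_u - 1); expected: over all
    ordered pairs of pooled pairable values.
    """
    units = [row[~np.isnan(row)] for row in values]
    units = [u for u in units if u.size >= 2]
    pooled = np.concatenate(units)
    domain = np.unique(pooled)
    # per-value pooled multiplicities for the ordinal metric
    n_g = {v: np.sum(pooled == v) for v in domain}

    def dist(a, b):
        if a == b:
            return 0.0
        if level == "nominal":
            return 1.0
        if level == "interval":
            return (a - b) ** 2
        lo, hi = min(a, b), max(a, b)
        s = sum(n_g[g] for g in domain if lo <= g <= hi)
        return (s - (n_g[a] + n_g[b]) / 2.0) ** 2

    num = den_n = 0.0
    for u in units:
        m = u.size
        for i in range(m):
            for j in range(m):
                if i != j:
                    num += dist(u[i], u[j]) / (m - 1)
        den_n += m
    d_obs = num / den_n
    tot = 0.0
    for a in pooled:
        for b in pooled:
            tot += dist(a, b)
    d_exp = tot / (den_n * (den_n - 1))
    return 1.0 - d_obs / d_exp


def kappa_bruteforce(a, b, weights):
    from sklearn.metrics import cohen_kappa_score
    return cohen_kappa_score(a, b, weights=weights)


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------

class TestKrippendorffAlpha:
    def test_perfect_agreement_is_one(self):
        m = agreement.RatingMatrix(np.tile([[1, 2, 3, 1]], (3, 1)).T,
                                   level="ordinal")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert agreement.krippendorff_alpha(m) == 1.0

    @pytest.mark.parametrize("level", ["nominal", "ordinal", "interval"])
    def test_matches_bruteforce_small_matrices(self, level):
        rng = np.random.default_rng(7)
        for _ in range(6):
            vals = rng.integers(0, 4, size=(8, 3)).astype(float)
            vals[rng.random(vals.shape) < 0.15] = np.nan
            keep = (~np.isnan(vals)).sum(axis=1) >= 2
            vals = vals[keep]
            m = agreement.RatingMatrix(vals, level=level)
            ours = agreement.krippendorff_alpha(m)
            ref = alpha_bruteforce(vals, level)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_unit_permutation_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.integers(0, 3, size=(10, 2)).astype(float)
        a1 = agreement.krippendorff_alpha(
            agreement.RatingMatrix(vals, level="ordinal"))
        a2 = agreement.krippendorff_alpha(
            agreement.RatingMatrix(vals[rng.permutation(10)],
                                   level="ordinal"))
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_injected_disagreement_lowers_alpha(self):
        vals = np.tile(np.arange(6.0)[:, None], (1, 2))
        perfect = agreement.krippendorff_alpha(
            agreement.RatingMatrix(vals, level="interval"))
        vals2 = vals.copy()
        vals2[0, 1] = 5.0
        worse = agreement.krippendorff_alpha(
            agreement.RatingMatrix(vals2, level="interval"))
        assert worse < perfect


# ---------------------------------------------------------------------------
# weighted kappa
# ---------------------------------------------------------------------------

class TestWeightedKappa:
    def test_identical_vectors(self):
        assert agreement.weighted_kappa([0, 1, 2, 3], [0, 1, 2, 3]) == 1.0

    def test_hand_computed_three_categories(self):
        # n=10 confusion table: diag (3,2,2); off-diag (0,1)=1, (1,2)=1,
        # (2,0)=1; linear weights, k=3
        a = [0, 0, 0, 1, 1, 2, 2, 0, 1, 2]
        b = [0, 0, 0, 1, 1, 2, 2, 1, 2, 0]
        ours = agreement.weighted_kappa(a, b, "linear")
        ref = kappa_bruteforce(a, b, "linear")
        assert ours == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("weights", ["linear", "quadratic"])
    def test_matches_sklearn_random_tables(self, weights):
        rng = np.random.default_rng(11)
        for _ in range(8):
            a = rng.integers(0, 4, 12)
            b = np.where(rng.random(12) < 0.6, a, rng.integers(0, 4, 12))
            ours = agreement.weighted_kappa(a, b, weights)
            ref = kappa_bruteforce(a, b, weights)
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_invariant_under_order_preserving_relabeling(self):
        a = np.array([0, 1, 2, 1, 0, 2, 2, 1])
        b = np.array([0, 1, 1, 1, 0, 2, 2, 0])
        assert agreement.weighted_kappa(a, b) == pytest.approx(
            agreement.weighted_kappa(10 + 5 * a, 10 + 5 * b), abs=1e-12)


# ---------------------------------------------------------------------------
# ICC(A,1)
# ---------------------------------------------------------------------------

class TestICC:
    def test_self_agreement_is_one(self):
        a = [1.0, 2.0, 5.0, 3.0, 8.0, 4.0]
        icc, lo, hi = agreement.icc_a1(a, a)
        assert icc == pytest.approx(1.0)

    def test_matches_pingouin_icc2(self):
        import pandas as pd
        import pingouin as pg
        rng = np.random.default_rng(5)
        a = rng.normal(10, 3, 12)
        b = a + rng.normal(0.5, 1.0, 12)
        icc, lo, hi = agreement.icc_a1(a, b)
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(12), 2),
            "raters": np.tile(["A", "B"], 12),
            "score": np.column_stack([a, b]).ravel()})
        ref = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="score")
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = row[[c for c in ref.columns if c.startswith("CI95")][0]]
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        assert lo == pytest.approx(ci[0], abs=0.01)   # pingouin rounds the CI
        assert hi == pytest.approx(ci[1], abs=0.01)

    def test_constant_offset_penalized(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        icc, _, _ = agreement.icc_a1(a, a + 2.0)
        assert icc < 1.0
        assert np.corrcoef(a, a + 2.0)[0, 1] == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        assert agreement.icc_a1([2.0] * 5, [2.0] * 5) == (None, None, None)


# ---------------------------------------------------------------------------
# Kendall tau-b and diagnostic concordance
# ---------------------------------------------------------------------------

class TestTauAndDiagnosis:
    def test_tau_matches_scipy(self):
        from scipy.stats import kendalltau
        rng = np.random.default_rng(9)
        for _ in range(6):
            a = rng.integers(0, 5, 12).astype(float)
            b = rng.integers(0, 5, 12).astype(float)
            if np.unique(a).size < 2 or np.unique(b).size < 2:
                continue
            assert agreement.kendall_tau_b(a, b) == pytest.approx(
                kendalltau(a, b).statistic, abs=1e-10)

    def test_perfect_prediction(self):
        out = agreement.diagnostic_concordance(
            ["N+", "N-", "N+"], ["N+", "N-", "N+"])
        assert (out["accuracy_pct"], out["sensitivity_pct"],
                out["specificity_pct"]) == (100.0, 100.0, 100.0)

    def test_toy_confusion_counts(self):
        ref = ["N+"] * 5 + ["N-"] * 5
        pred = ["N+"] * 5 + ["N+"] + ["N-"] * 4
        out = agreement.diagnostic_concordance(ref, pred)
        assert out["sensitivity_pct"] == 100.0
        assert out["specificity_pct"] == 80.0
        assert out["accuracy_pct"] == 90.0

    def test_always_positive_predictor(self):
        out = agreement.diagnostic_concordance(
            ["N+", "N-", "N-", "N+"], ["N+"] * 4)
        assert out["sensitivity_pct"] == 100.0
        assert out["specificity_pct"] == 0.0

    def test_missing_class_reported_missing(self):
        out = agreement.diagnostic_concordance(["N+", "N+"], ["N+", "N-"])
        assert out["specificity_pct"] is None

    def test_auc_perfect_separation(self):
        out = agreement.diagnostic_concordance(
            ["N+", "N+", "N-", "N-"], ["N+", "N+", "N-", "N-"],
            scores=[1.0, 2.0, 9.0, 8.0])
        assert out["auc"] == 1.0


class TestConcordancePanel:
    def test_summary_fields(self):
        res = agreement.concordance([1, 2, 3, 4, 5], [1, 2, 3, 5, 7])
        assert res.exact_agreement_pct == 60.0
        assert res.within_one_pct == 80.0
        assert res.mean_absolute_difference == pytest.approx(0.6)
        assert res.weighted_kappa is not None and res.icc is not None
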