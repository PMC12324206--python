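import math

import numpy as np
import pytest

from kinesig.errors import DataError
from kinesig.stats import (
    balanced_accuracy,
    bonferroni,
    icc_absolute_single,
    icc_consistency_single,
    ks_two_sided,
    mcnemar_test,
    signature_tests,
)


def exact_mcnemar_oracle(n01: int, n10: int) -> float:
    """Two-sided exact binomial p by direct enumeration."""
    n = n01 + n10
    if n == 0:
        return 1.0
    k = min(n01, n10)
    tail = sum(math.comb(n, j) for j in range(k + 1)) / 2**n
    if n01 == n10:
        return 1.0
    return min(1.0, 2 * tail)


def ks_d_oracle(a, b) -> float:
    """Brute-force sup |ECDF_a - ECDF_b| over all pooled breakpoints."""
    pooled = np.concatenate([a, b])
    best = 0.0
    for x in pooled:
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestBalancedAccuracy:
    def test_majority_predictor_is_half(self):
        y = np.array(["DM"] * 58 + ["FSHD"] * 28)
        pred = np.array(["DM"] * 86)
        assert balanced_accuracy(y, pred) == 0.5

    def test_identity_is_one(self):
        y = np.array(["A", "B", "A", "B"])
        assert balanced_accuracy(y, y) == 1.0

    def test_confusion_matrix_oracle(self):
        y = np.array(["A", "A", "A", "B"])
        p = np.array(["A", "A", "B", "B"])
        assert balanced_accuracy(y, p) == pytest.approx((2 / 3 + 1) / 2)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["A", "B"], 40)
        p = rng.choice(["A", "B"], 40)
        swap = {"A": "B", "B": "A"}
        y2 = np.array([swap[v] for v in y])
        p2 = np.array([swap[v] for v in p])
        assert balanced_accuracy(y, p) == pytest.approx(balanced_accuracy(y2, p2))

    def test_sklearn_cross_check(self):
        from sklearn.metrics import balanced_accuracy_score

        rng = np.random.default_rng(3)
        y = rng.choice(["A", "B", "C"], 60)
        p = rng.choice(["A", "B", "C"], 60)
        assert balanced_accuracy(y, p) == pytest.approx(balanced_accuracy_score(y, p))

    def test_predicted_only_class_rejected(self):
        with pytest.raises(DataError):
            balanced_accuracy(np.array(["A", "A"]), np.array(["A", "B"]))


class TestMcnemar:
    @pytest.mark.parametrize(
        "n01,n10,expected",
        [(5, 5, 1.0), (0, 0, 1.0), (8, 1, 20 / 512)],
    )
    def test_known_values(self, n01, n10, expected):
        assert mcnemar_test(n01, n10) == pytest.approx(expected)

    def test_symmetry(self):
        for a, b in [(3, 9), (0, 7), (12, 2), (40, 25)]:
            assert mcnemar_test(a, b) == pytest.approx(mcnemar_test(b, a))

    def test_exact_matches_enumeration(self):
        for n in range(13):
            for n01 in range(n + 1):
                got = mcnemar_test(n01, n - n01)
                assert got == pytest.approx(
                    exact_mcnemar_oracle(n01, n - n01), abs=1e-12
                ), (n01, n - n01)

    def test_large_counts_use_continuity_corrected_chi2(self):
        from scipy.stats import chi2

        p = mcnemar_test(40, 20)
        assert p == pytest.approx(chi2.sf((abs(40 - 20) - 1) ** 2 / 60, 1))

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            mcnemar_test(-1, 2)


class TestKs:
    def test_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        d, p = ks_two_sided(a, a)
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sided([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_ecdf_sweep_example(self):
        d, _ = ks_two_sided([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_brute_force_oracle_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n, m = rng.integers(3, 15, 2)
            a = np.round(rng.normal(size=n), 1)  # rounding forces ties
            b = np.round(rng.normal(size=m), 1)
            d, _ = ks_two_sided(a, b)
            assert d == pytest.approx(ks_d_oracle(a, b), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=20), rng.normal(size=25)
        d0, _ = ks_two_sided(a, b)
        d1, _ = ks_two_sided(np.exp(a), np.exp(b))
        assert d0 == pytest.approx(d1)

    def test_type_one_calibration(self):
        """Under identical Gaussian distributions (n=30 per group) the raw
        rejection fraction at alpha=0.05 sits in 0.05 +/- 0.02."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            _, p = ks_two_sided(rng.normal(size=30), rng.normal(size=30))
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) <= 0.02


class TestBonferroni:
    def test_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.001, 0.5], 34), [0.034, 1.0])

    def test_monotone_in_p(self):
        p = np.linspace(0, 0.2, 20)
        adj = bonferroni(p, 34)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)


class TestIcc:
    def test_perfect_agreement(self):
        m = np.column_stack([np.arange(6.0), np.arange(6.0)])
        rep = icc_absolute_single(m)
        assert rep.icc == pytest.approx(1.0)
        assert rep.category == "excellent"

    def test_offset_penalized_vs_consistency(self):
        rng = np.random.default_rng(1)
        s1 = rng.normal(10, 2, 20)
        m = np.column_stack([s1, s1 + 5.0])
        assert icc_absolute_single(m).icc < icc_consistency_single(m)

    def test_variance_components_simulation(self):
        """sigma^2_subj=4, sigma^2_err=1 -> ICC -> 4/5 at n=500."""
        rng = np.random.default_rng(9)
        n, k = 500, 2
        subj = rng.normal(0, 2.0, n)[:, None]
        m = 10 + subj + rng.normal(0, 1.0, (n, k))
        assert icc_absolute_single(m).icc == pytest.approx(0.8, rel=0.05)

    def test_pingouin_cross_check(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(12)
        m = rng.normal(10, 2, (8, 2)) + rng.normal(0, 1, (8, 1))
        rep = icc_absolute_single(m)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 2),
                "rater": np.tile([0, 1], 8),
                "score": m.ravel(),
            }
        )
        icc2 = pg.intraclass_corr(df, "subject", "rater", "score")
        ref = float(
            icc2.loc[icc2["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0]
        )
        assert rep.icc == pytest.approx(ref, abs=1e-6)

    def test_estimate_never_exceeds_one(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            m = rng.normal(size=(6, 3))
            assert icc_absolute_single(m).icc <= 1.0 + 1e-12

    def test_missing_cells_rejected(self):
        m = np.array([[1.0, np.nan], [2.0, 2.0]])
        with pytest.raises(DataError):
            icc_absolute_single(m)

    @pytest.mark.parametrize(
        "icc,cat",
        [(0.2, "poor"), (0.6, "moderate"), (0.8, "good"), (0.95, "excellent")],
    )
    def test_category_cutpoints(self, icc, cat):
        from kinesig.stats import _icc_category

        assert _icc_category(icc) == cat


class TestSignatureTable:
    def test_bonferroni_consistency(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        a = pd.DataFrame({"f1": rng.normal(0, 1, 30), "f2": rng.normal(0, 1, 30)})
        b = pd.DataFrame({"f1": rng.normal(3, 1, 30), "f2": rng.normal(0, 1, 30)})
        res = signature_tests(a, b, ["f1", "f2"])
        for r in res:
            assert r.p_bonferroni >= r.p_raw
            assert r.significant == (r.p_bonferroni < 0.05)
        assert res[0].significant and not res[1].significant
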