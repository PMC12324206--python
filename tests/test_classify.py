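import itertools
import math

import numpy as np
import pytest

from kinesig.classify import (
    ClassificationResult,
    compare_models,
    importance_ranking,
    loso_linear_svc,
    shap_linear,
)
from kinesig.errors import DataError, StratificationError


def _two_group_data(n=40, sep=3.0, n_features=5, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
    X = rng.normal(0, 1, (n, n_features))
    X[y == "B", 0] += sep
    return X, y


def exhaustive_shapley(w, intercept, x, mu):
    """Shapley values of a linear value function by full subset enumeration,
    with absent features imputed at the background mean."""
    k = len(w)
    phi = np.zeros(k)

    def value(subset):
        z = mu.copy()
        for j in subset:
            z[j] = x[j]
        return intercept + w @ z

    for j in range(k):
        others = [i for i in range(k) if i != j]
        for r in range(k):
            for subset in itertools.combinations(others, r):
                weight = (
                    math.factorial(r) * math.factorial(k - r - 1)
                    / math.factorial(k)
                )
                phi[j] += weight * (value(set(subset) | {j}) - value(set(subset)))
    return phi


class TestLosoSvc:
    def test_separable_groups_near_bayes_accuracy(self):
        """Group means 3 pooled-SD apart: the Bayes balanced accuracy for
        two unit-variance Gaussians at Mahalanobis distance d is Phi(d/2) =
        Phi(1.5) ~ 0.933; LOSO should approach it."""
        from scipy.stats import norm

        X, y = _two_group_data(n=40, sep=3.0)
        res = loso_linear_svc(X, y, seed=0)
        bayes = norm.cdf(1.5)
        assert res.balanced_accuracy == pytest.approx(bayes, abs=0.08)
        assert res.balanced_accuracy >= 0.85

    def test_permuted_labels_at_chance(self):
        X, y = _two_group_data(n=40, sep=3.0)
        rng = np.random.default_rng(1)
        accs = []
        for _ in range(10):
            yp = rng.permutation(y)
            accs.append(loso_linear_svc(X, yp, seed=0).balanced_accuracy)
        assert abs(np.mean(accs) - 0.5) <= 0.1

    def test_one_fold_per_subject(self):
        X, y = _two_group_data(n=17)
        res = loso_linear_svc(X, y, seed=0)
        assert len(res.y_pred) == 17
        assert len(res.selected_c) == 17

    def test_deterministic_given_seed(self):
        X, y = _two_group_data(n=24, sep=1.0, seed=5)
        r1 = loso_linear_svc(X, y, seed=3)
        r2 = loso_linear_svc(X, y, seed=3)
        assert np.array_equal(r1.y_pred, r2.y_pred)
        assert r1.selected_c == r2.selected_c

    def test_standardization_never_sees_held_out_subject(self):
        """Fold scaler statistics must equal statistics recomputed from the
        training subjects alone, even after an extreme shift of the held-out
        subject's raw features."""
        X, y = _two_group_data(n=20, sep=1.5, seed=2)
        X2 = X.copy()
        X2[7] = X2[7] * 50 + 1000.0
        res = loso_linear_svc(X2, y, seed=0)
        pid = res.participant_ids[7]
        mean, scale = res.fold_scaler_stats[pid]
        mask = np.ones(len(y), bool)
        mask[7] = False
        np.testing.assert_allclose(mean, X2[mask].mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(scale, X2[mask].std(axis=0), atol=1e-12)

    def test_tiny_class_raises_stratification_error(self):
        X = np.random.default_rng(0).normal(size=(8, 3))
        y = np.array(["A"] * 6 + ["B"] * 2)
        with pytest.raises((StratificationError, DataError)):
            loso_linear_svc(X, y, seed=0)


class TestLinearShap:
    def test_zero_weight_feature_zero_contribution(self):
        rng = np.random.default_rng(0)
        Xb = rng.normal(size=(20, 3))
        rep = shap_linear(np.array([1.0, 0.0, -2.0]), 0.5, Xb, Xb)
        assert np.all(rep.shap_values[:, 1] == 0)

    def test_local_accuracy(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=4)
        b = 0.3
        Xb = rng.normal(size=(30, 4))
        Xe = rng.normal(size=(6, 4))
        rep = shap_linear(w, b, Xb, Xe)
        scores = Xe @ w + b
        np.testing.assert_allclose(
            rep.base_value + rep.shap_values.sum(axis=1), scores, atol=1e-8
        )

    def test_single_feature_closed_form(self):
        Xb = np.array([[1.0], [3.0]])
        rep = shap_linear(np.array([2.0]), 0.0, Xb, np.array([[5.0]]))
        assert rep.shap_values[0, 0] == pytest.approx(2.0 * (5.0 - 2.0))

    def test_matches_exhaustive_shapley_enumeration(self):
        rng = np.random.default_rng(2)
        for k in (2, 3, 5):
            w = rng.normal(size=k)
            b = rng.normal()
            Xb = rng.normal(size=(15, k))
            x = rng.normal(size=k)
            rep = shap_linear(w, b, Xb, x[None, :])
            phi = exhaustive_shapley(w, b, x, Xb.mean(axis=0))
            np.testing.assert_allclose(rep.shap_values[0], phi, atol=1e-8)

    def test_empty_background_rejected(self):
        with pytest.raises(DataError):
            shap_linear(np.array([1.0]), 0.0, np.empty((0, 1)), np.array([[1.0]]))


def _result(ids, y_true, y_pred, shap=None, names=None):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    from kinesig.stats import balanced_accuracy

    return ClassificationResult(
        model_name="m",
        input_set="video_all",
        participant_ids=ids,
        y_true=y_true,
        y_pred=y_pred,
        decision_scores=np.zeros(len(ids)),
        balanced_accuracy=balanced_accuracy(y_true, y_pred),
        shap_values=shap,
        feature_names=names,
    )


class TestComparisons:
    def test_identical_predictions(self):
        ids = list("abcd")
        y = ["A", "A", "B", "B"]
        r = _result(ids, y, y)
        out = compare_models(r, r)
        assert (out["n01"], out["n10"], out["p"]) == (0, 0, 1.0)

    def test_one_sided_discordance(self):
        ids = list("abcde")
        y = np.array(["A", "A", "B", "B", "A"])
        a = _result(ids, y, y)  # all correct
        wrong = y.copy()
        wrong[:3] = np.where(wrong[:3] == "A", "B", "A")
        b = _result(ids, y, wrong)
        out = compare_models(a, b)
        assert (out["n01"], out["n10"]) == (3, 0)

    def test_cross_checked_against_stats_oracle(self):
        from kinesig.stats import mcnemar_test

        ids = [str(i) for i in range(12)]
        rng = np.random.default_rng(0)
        y = rng.choice(["A", "B"], 12)
        pa = rng.choice(["A", "B"], 12)
        pb = rng.choice(["A", "B"], 12)
        out = compare_models(_result(ids, y, pa), _result(ids, y, pb))
        assert out["p"] == pytest.approx(mcnemar_test(out["n01"], out["n10"]))


class TestImportanceRanking:
    def test_single_active_feature_ranks_first(self):
        shap = np.zeros((10, 4))
        shap[:, 2] = 1.5
        r = _result(list("abcdefghij"), ["A"] * 5 + ["B"] * 5,
                    ["A"] * 5 + ["B"] * 5, shap, ["f0", "f1", "f2", "f3"])
        ranked = importance_ranking(r)
        assert ranked.iloc[0]["feature"] == "f2"

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(3)
        shap = rng.normal(size=(8, 3))
        names = ["x", "y", "z"]
        r1 = _result(list("abcdefgh"), ["A"] * 4 + ["B"] * 4,
                     ["A"] * 4 + ["B"] * 4, shap, names)
        perm = [2, 0, 1]
        r2 = _result(list("abcdefgh"), ["A"] * 4 + ["B"] * 4,
                     ["A"] * 4 + ["B"] * 4, shap[:, perm],
                     [names[i] for i in perm])
        t1 = importance_ranking(r1).set_index("feature")["mean_abs_shap"]
        t2 = importance_ranking(r2).set_index("feature")["mean_abs_shap"]
        for f in names:
            assert t1[f] == pytest.approx(t2[f])

    def test_planted_upper_limb_effects_dominate(self):
        """A cohort whose only planted group differences are upper-limb
        (shoulder/elbow) must rank upper-limb features on top for the
        disease-vs-control model."""
        from kinesig.pipeline import build_design, cohort_from_bundle
        from kinesig.synth import (
            GroupEffects,
            SyntheticCohortConfig,
            generate_cohort,
        )

        effects = {
            "CTL": GroupEffects(),
            "FSHD": GroupEffects(shoulder_abd_max=110.0, elbow_flex_compensation=40.0),
            "DM": GroupEffects(),
        }
        cfg = SyntheticCohortConfig(
            n_fshd=12, n_dm=0, n_ctl=12, seed=77, effects=effects
        )
        data = cohort_from_bundle(generate_cohort(cfg))
        ids, X, y, names = build_design(data, ("FSHD", "CTL"), "video_all")
        res = loso_linear_svc(X, y, ids, seed=0, feature_names=names)
        ranked = importance_ranking(res)
        top3 = ranked.head(3)["feature"].tolist()
        upper = {e.name for e in data.registry.entries if e.provenance == "upper_limb"}
        assert all(f in upper for f in top3), top3
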