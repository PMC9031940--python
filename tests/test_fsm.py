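"""Ranking methods against constructed oracles and invariant properties."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

from ictalsel.fsm import (
    FsmConfig,
    LimeConfig,
    Ranking,
    ShapConfig,
    aggregate_instance_importance,
    kmeans_background,
    rank_dt_gini,
    rank_erf_permutation,
    rank_kernel_shap,
    rank_lime,
    rank_svm_weights,
    ranking_subsample,
    reciprocal_rank_fusion,
    shap_values_instance,
)


class LogisticModel:
    """Analytic stand-in classifier: sigmoid of a fixed linear score."""

    def __init__(self, weights, intercept=0.0):
        self.w = np.asarray(weights, float)
        self.b = intercept

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-(np.asarray(X) @ self.w + self.b)))
        return np.column_stack([1 - p, p])


def separable_data(rng, n=200, n_features=6, informative=0, gap=4.0):
    """Noise features plus one feature that perfectly separates the classes."""
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, n_features))
    X[:, informative] = y * gap + rng.uniform(-1, 1, n)
    return X, y


def exact_shapley(x, model, background):
    """Brute-force 2^M Shapley values of the imputation value function."""
    M = len(x)

    def value(subset):
        synth = background.copy()
        for j in subset:
            synth[:, j] = x[j]
        return model.predict_proba(synth)[:, 1].mean()

    phi = np.zeros(M)
    for j in range(M):
        others = [f for f in range(M) if f != j]
        for size in range(M):
            for S in combinations(others, size):
                w = factorial(size) * factorial(M - size - 1) / factorial(M)
                phi[j] += w * (value(S + (j,)) - value(S))
    return phi


class TestRankingContainer:
    def test_order_sorts_scores_descending_with_stable_ties(self):
        r = Ranking(["a", "b", "c", "d"], [0.5, 0.9, 0.5, 0.1], method="x")
        assert r.order == ["b", "a", "c", "d"]
        assert r.positions() == {"b": 1, "a": 2, "c": 3, "d": 4}

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            Ranking(["a"], [-0.1], method="x")

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd
        r = Ranking(["a", "b"], [0.2, 0.8], method="x")
        r.to_csv(tmp_path / "r.csv")
        df = pd.read_csv(tmp_path / "r.csv")
        assert list(df.feature_name) == ["b", "a"]
        assert list(df["rank"]) == [1, 2]


class TestDtGini:
    def test_separating_feature_scores_highest(self, rng):
        X, y = separable_data(rng, informative=2)
        r = rank_dt_gini(X, y, [f"f{i}" for i in range(6)])
        assert r.order[0] == "f2"
        # exhaustive stump oracle: f2 admits a pure single split, so its
        # importance must account for (essentially) all impurity decrease
        assert r.scores[2] >= 0.95

    def test_unused_feature_scores_zero(self, rng):
        X, y = separable_data(rng, informative=0, gap=10.0)
        r = rank_dt_gini(X, y, [f"f{i}" for i in range(6)])
        assert np.all(r.scores[1:] == 0.0)

    def test_scores_sum_to_one(self, rng):
        X = rng.standard_normal((100, 4))
        y = (X[:, 0] + 0.3 * X[:, 1] + rng.standard_normal(100) > 0).astype(int)
        r = rank_dt_gini(X, y, list("abcd"))
        assert np.sum(r.scores) == pytest.approx(1.0, abs=1e-9)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_dt_gini(rng.standard_normal((10, 2)), np.zeros(10, int), ["a", "b"])


class TestSvmWeights:
    def test_informative_feature_tops(self, rng):
        X, y = separable_data(rng, n_features=5, informative=3)
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        r = rank_svm_weights(X, y, [f"f{i}" for i in range(5)])
        assert r.order[0] == "f3"
        assert np.all(r.scores >= 0)

    def test_duplicated_informative_weight_mass(self, rng):
        X, y = separable_data(rng, n_features=4, informative=0)
        X = np.column_stack([X, X[:, 0]])          # duplicate informative col
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        r = rank_svm_weights(X, y, [f"f{i}" for i in range(5)])
        assert r.scores[0] + r.scores[4] > max(r.scores[1:4])


class TestAggregate:
    def test_abs_then_mean(self):
        agg = aggregate_instance_importance(np.array([[1.0], [-1.0]]))
        assert agg[0] == 1.0

    def test_single_instance_is_abs(self):
        agg = aggregate_instance_importance(np.array([[-2.0, 0.5]]))
        assert np.allclose(agg, [2.0, 0.5])

    def test_all_zero(self):
        assert np.all(aggregate_instance_importance(np.zeros((3, 4))) == 0.0)


class TestLime:
    def test_dominant_coefficient_recovered(self, rng):
        model = LogisticModel([3.0, 0.0, 0.0])
        X = rng.uniform(0, 1, (30, 3))
        cfg = FsmConfig(lime=LimeConfig(n_explain=10, seed=0))
        r = rank_lime(X, None, model, ["x1", "x2", "x3"], cfg)
        assert r.order[0] == "x1"

    def test_ignored_feature_near_zero(self, rng):
        model = LogisticModel([2.0, -1.5, 0.0, 1.0])
        X = rng.uniform(0, 1, (40, 4))
        cfg = FsmConfig(lime=LimeConfig(n_explain=15, seed=1))
        r = rank_lime(X, None, model, list("abcd"), cfg)
        assert r.scores[2] < 0.05 * r.scores.max()

    def test_seeded_determinism(self, rng):
        model = LogisticModel([1.0, -2.0])
        X = rng.uniform(0, 1, (20, 2))
        cfg = FsmConfig(lime=LimeConfig(n_explain=5, seed=7))
        a = rank_lime(X, None, model, ["a", "b"], cfg)
        b = rank_lime(X, None, model, ["a", "b"], cfg)
        assert np.array_equal(a.scores, b.scores)

    def test_model_without_score_output_rejected(self, rng):
        class Opaque:
            pass
        with pytest.raises(TypeError):
            rank_lime(rng.uniform(0, 1, (5, 2)), None, Opaque(), ["a", "b"],
                      FsmConfig(lime=LimeConfig(n_explain=2)))


class TestKernelShap:
    @pytest.mark.parametrize("M", [4, 7, 10])
    def test_full_enumeration_matches_exact_shapley(self, M, rng):
        model = LogisticModel(rng.normal(size=M))
        background = rng.normal(size=(6, M))
        x = rng.normal(size=M)
        phi = shap_values_instance(x, model, background, enum_limit=12)
        oracle = exact_shapley(x, model, background)
        assert np.max(np.abs(phi - oracle)) < 1e-6

    def test_local_accuracy_constraint(self, rng):
        M = 6
        model = LogisticModel(rng.normal(size=M))
        background = rng.normal(size=(5, M))
        x = rng.normal(size=M)
        phi = shap_values_instance(x, model, background)
        fx = model.predict_proba(x[None, :])[0, 1]
        f0 = model.predict_proba(background)[:, 1].mean()
        assert phi.sum() == pytest.approx(fx - f0, abs=1e-6)

    def test_ignored_feature_zero_attribution(self, rng):
        model = LogisticModel([1.0, 0.0, -2.0])
        background = rng.normal(size=(5, 3))
        phi = shap_values_instance(rng.normal(size=3), model, background)
        assert abs(phi[1]) < 1e-9

    def test_sampled_coalitions_rank_informative_first(self, rng):
        M = 16                                     # above the enumeration limit
        w = np.zeros(M)
        w[5] = 4.0
        model = LogisticModel(w)
        X = rng.uniform(0, 1, (30, M))
        cfg = FsmConfig(shap=ShapConfig(n_explain=8, n_coalitions=600, seed=2))
        r = rank_kernel_shap(X, None, model, [f"f{i}" for i in range(M)], cfg,
                             background=rng.uniform(0, 1, (10, M)))
        assert r.order[0] == "f5"

    def test_empty_background_rejected(self, rng):
        model = LogisticModel([1.0, 1.0])
        with pytest.raises(ValueError):
            shap_values_instance(np.zeros(2), model, np.empty((0, 2)))

    def test_kmeans_background_shape(self, rng):
        bg = kmeans_background(rng.normal(size=(100, 3)), k=8, seed=0)
        assert bg.shape == (8, 3)
        # fewer rows than k degrades gracefully
        assert kmeans_background(rng.normal(size=(4, 3)), k=8).shape == (4, 3)


class TestErfPermutation:
    def make_split(self, rng, informative=1):
        X, y = separable_data(rng, n=300, n_features=5, informative=informative)
        return X[:150], y[:150], X[150:], y[150:]

    def test_informative_feature_strictly_largest(self, rng):
        Xtr, ytr, Xho, yho = self.make_split(rng, informative=1)
        r = rank_erf_permutation(Xtr, ytr, [f"f{i}" for i in range(5)], Xho, yho)
        assert r.order[0] == "f1"
        assert r.scores[1] > max(np.delete(r.scores, 1))

    def test_noise_features_near_zero(self, rng):
        Xtr, ytr, Xho, yho = self.make_split(rng, informative=1)
        r = rank_erf_permutation(Xtr, ytr, [f"f{i}" for i in range(5)], Xho, yho)
        assert np.all(np.delete(r.scores, 1) < 0.02)

    def test_seeded_reproducibility(self, rng):
        Xtr, ytr, Xho, yho = self.make_split(rng)
        names = [f"f{i}" for i in range(5)]
        a = rank_erf_permutation(Xtr, ytr, names, Xho, yho)
        b = rank_erf_permutation(Xtr, ytr, names, Xho, yho)
        assert np.array_equal(a.scores, b.scores)

    def test_single_class_holdout_rejected(self, rng):
        Xtr, ytr, Xho, yho = self.make_split(rng)
        with pytest.raises(ValueError):
            rank_erf_permutation(Xtr, ytr, [f"f{i}" for i in range(5)],
                                 Xho, np.zeros_like(yho))


class TestReciprocalRankFusion:
    def test_unanimous_first_place(self):
        rankings = [Ranking(list("abc"), [3 - i for i in range(3)], method=f"m{j}")
                    for j in range(5)]
        fused = reciprocal_rank_fusion(rankings)
        # r(a) = 1 / (5 * 1/1) = 0.2; stored score is its reciprocal
        assert fused.order[0] == "a"
        assert fused.scores[0] == pytest.approx(5.0)

    def test_identical_rankings_preserve_order(self):
        base = Ranking(list("abcd"), [0.1, 0.9, 0.5, 0.3], method="m")
        fused = reciprocal_rank_fusion([base, base])
        assert fused.order == base.order

    def test_hand_computed_fusion_value(self):
        # feature ranked 2nd and 3rd: r(f) = 1/(1/2 + 1/3) = 1.2
        r1 = Ranking(list("abc"), [3, 2, 1], method="x")   # b is 2nd
        r2 = Ranking(list("abc"), [3, 1, 2], method="y")   # b is 3rd
        fused = reciprocal_rank_fusion([r1, r2])
        idx = fused.feature_names.index("b")
        assert 1.0 / fused.scores[idx] == pytest.approx(1.2)

    def test_mismatched_universes_rejected(self):
        r1 = Ranking(["a", "b"], [1, 2], method="x")
        r2 = Ranking(["a", "c"], [1, 2], method="y")
        with pytest.raises(ValueError):
            reciprocal_rank_fusion([r1, r2])


class TestRankingSubsample:
    def test_stratified_half(self):
        y = np.r_[np.ones(20, int), np.zeros(180, int)]
        X = np.arange(200, dtype=float)[:, None]
        Xs, ys = ranking_subsample(X, y, 0.5, seed=0)
        assert ys.sum() == 10 and len(ys) == 100

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((50, 2))
        y = rng.integers(0, 2, 50)
        a = ranking_subsample(X, y, 0.5, seed=4)
        b = ranking_subsample(X, y, 0.5, seed=4)
        assert np.array_equal(a[0], b[0])


class TestPlantedRecovery:
    """All six rankers find a planted discriminative feature in their top 10."""

    def test_every_fsm_hits_ground_truth_top10(
        self, planted_features, planted_ground_truth
    ):
        from ictalsel.evaluate import CLASSIFIER_CONFIGS
        from ictalsel.pipeline import compute_rankings

        cfg = FsmConfig(
            lime=LimeConfig(n_explain=25, seed=3),
            shap=ShapConfig(n_explain=8, n_coalitions=300, seed=3),
        )
        rankings = compute_rankings(
            planted_features, CLASSIFIER_CONFIGS["FS1"]["RF"], cfg,
            ("dt", "svm", "lime", "shap", "erf", "rr"), seed=11,
        )
        assert set(rankings) == {"dt", "svm", "lime", "shap", "erf", "rr"}
        for method, ranking in rankings.items():
            hits = set(ranking.top(10)) & planted_ground_truth
            assert hits, f"{method} found no planted feature in its top 10"
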