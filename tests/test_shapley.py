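"""Exact Shapley attribution: oracles and game-theoretic axioms."""

import itertools
from math import factorial

import numpy as np
import pandas as pd
import pytest

from epiloop.gbm import BoostedForest, RegressionTree, fit_gbm
from epiloop.shapley import (InterventionalExplainer, coalition_value,
                             dependence_data, exact_shap,
                             mean_abs_shap_by_direction, sample_background,
                             shap_matrix, waterfall)
from .conftest import make_tiny_params


def stump(feature, threshold, left_value, right_value):
    """x[feature] <= threshold → left_value, else right_value."""
    return RegressionTree(
        feature=np.array([feature, -1, -1], dtype=np.int32),
        threshold=np.array([threshold, np.nan, np.nan]),
        threshold_bin=np.array([0, -1, -1], dtype=np.int32),
        left=np.array([1, -1, -1], dtype=np.int32),
        right=np.array([2, -1, -1], dtype=np.int32),
        value=np.array([0.0, left_value, right_value]),
        n_samples=np.array([2, 1, 1]),
    )


def make_forest(trees, names, base=0.0, lr=1.0):
    return BoostedForest(base_score=base, learning_rate=lr, trees=trees,
                         feature_names=list(names))


def permutation_shap(forest, x, background):
    """Average marginal contribution over all p! feature orderings."""
    p = forest.n_features
    phi = np.zeros(p)
    for perm in itertools.permutations(range(p)):
        members = []
        prev = coalition_value(forest, x, members, background)
        for i in perm:
            members.append(i)
            cur = coalition_value(forest, x, members, background)
            phi[i] += cur - prev
            prev = cur
    return phi / factorial(p)


def random_small_forest(rng, p=3, n=40, trees=5):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    params = make_tiny_params(n_estimators=trees, learning_rate=0.5,
                              max_leaves=4)
    return fit_gbm(X, y, params), X


class TestCoalitionValue:
    def test_full_coalition_is_the_prediction(self, rng):
        forest, X = random_small_forest(rng)
        v = coalition_value(forest, X[0], [0, 1, 2], X[:8])
        assert v == pytest.approx(float(forest.predict(X[:1])[0]))

    def test_empty_coalition_is_background_mean(self, rng):
        forest, X = random_small_forest(rng)
        v = coalition_value(forest, X[0], [], X[:8])
        assert v == pytest.approx(float(forest.predict(X[:8]).mean()))

    def test_single_split_tree_hand_enumeration(self):
        # f(x) = 1 if x0 > 0 else -1; background row has x0 = 1
        forest = make_forest([stump(0, 0.0, -1.0, 1.0)], ["a", "b"])
        x = np.array([-2.0, 5.0])
        bg = np.array([[1.0, 0.0]])
        assert coalition_value(forest, x, [], bg) == 1.0        # b's branch
        assert coalition_value(forest, x, [0], bg) == -1.0      # x's branch
        assert coalition_value(forest, x, [1], bg) == 1.0       # b decides
        assert coalition_value(forest, x, [0, 1], bg) == -1.0

    def test_empty_background_rejected(self, rng):
        forest, X = random_small_forest(rng)
        with pytest.raises(ValueError):
            coalition_value(forest, X[0], [0], np.empty((0, 3)))


class TestExactShap:
    def test_constant_forest_all_zero(self):
        tree = RegressionTree(
            feature=np.array([-1], dtype=np.int32),
            threshold=np.array([np.nan]),
            threshold_bin=np.array([-1], dtype=np.int32),
            left=np.array([-1], dtype=np.int32),
            right=np.array([-1], dtype=np.int32),
            value=np.array([3.0]), n_samples=np.array([5]))
        forest = make_forest([tree], ["a", "b"])
        expl = exact_shap(forest, np.array([1.0, 2.0]), np.zeros((4, 2)))
        assert (expl.phi == 0).all()
        assert expl.base_value == pytest.approx(3.0)

    def test_additive_stumps_with_symmetric_background(self):
        # f(x) = s(x0) + s(x1), s = ±1 step; background mean of s is 0
        forest = make_forest([stump(0, 0.0, -1.0, 1.0),
                              stump(1, 0.0, -1.0, 1.0)], ["a", "b"])
        bg = np.array([[-1.0, -1.0], [-1.0, 1.0], [1.0, -1.0], [1.0, 1.0]])
        expl = exact_shap(forest, np.array([2.0, -3.0]), bg)
        np.testing.assert_allclose(expl.phi.to_numpy(), [1.0, -1.0],
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        forest, X = random_small_forest(rng, p=3)
        bg = X[:7]
        x = X[-1]
        expl = exact_shap(forest, x, bg)
        oracle = permutation_shap(forest, x, bg)
        np.testing.assert_allclose(expl.phi.to_numpy(), oracle, atol=1e-10)

    def test_monte_carlo_permutation_agreement_p7(self, small_forest,
                                                  default_table):
        """p=7: sampled permutations agree within 3 standard errors."""
        rng = np.random.default_rng(5)
        X = default_table.X()
        bg = sample_background(X, 16, seed=5)
        x = X[11]
        expl = exact_shap(small_forest, x, bg)
        n_perm = 150
        draws = np.zeros((n_perm, 7))
        for k in range(n_perm):
            perm = rng.permutation(7)
            members = []
            prev = coalition_value(small_forest, x, members, bg)
            for i in perm:
                members.append(int(i))
                cur = coalition_value(small_forest, x, members, bg)
                draws[k, i] = cur - prev
                prev = cur
        mc = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(n_perm)
        assert (np.abs(mc - expl.phi.to_numpy()) <= 3 * se + 1e-12).all()


class TestExplainerFastPath:
    def test_fast_path_equals_direct_enumeration(self, rng):
        forest, X = random_small_forest(rng, p=3, trees=8)
        bg = X[:10]
        explainer = InterventionalExplainer(forest, bg)
        phi, base, pred = explainer.shap_values(X[:6])
        for i in range(6):
            expl = exact_shap(forest, X[i], bg)
            np.testing.assert_allclose(phi[i], expl.phi.to_numpy(),
                                       atol=1e-10)
            assert base == pytest.approx(expl.base_value, abs=1e-10)

    def test_additivity_on_many_rows(self, small_forest, default_table):
        X = default_table.X()[:50]
        bg = sample_background(default_table.X(), 64, seed=1)
        sm = shap_matrix(small_forest, X, bg)
        gaps = np.abs(sm.df["base_value"] + sm.phi().sum(axis=1)
                      - sm.df["prediction"])
        assert gaps.max() < 1e-8

    def test_dummy_feature_gets_exactly_zero(self):
        forest = make_forest([stump(0, 0.0, -1.0, 1.0)], ["a", "b", "c"])
        rng = np.random.default_rng(0)
        bg = rng.normal(size=(16, 3))
        expl = exact_shap(forest, np.array([0.5, 2.0, -2.0]), bg)
        assert expl.phi["b"] == 0.0
        assert expl.phi["c"] == 0.0

    def test_symmetry_of_duplicated_features(self):
        # identical stumps on two features; evaluate where x0 == x1
        forest = make_forest([stump(0, 0.0, 0.0, 1.0),
                              stump(1, 0.0, 0.0, 1.0)], ["a", "b"])
        bg = np.array([[-1.0, -1.0], [1.0, 1.0]])
        expl = exact_shap(forest, np.array([2.0, 2.0]), bg)
        assert expl.phi["a"] == pytest.approx(expl.phi["b"], abs=1e-8)

    def test_linearity_over_forest_sum(self, rng):
        t1 = stump(0, 0.0, -1.0, 2.0)
        t2 = stump(1, 0.5, 1.0, -0.5)
        bg = rng.normal(size=(12, 2))
        x = np.array([0.7, 0.1])
        f1 = make_forest([t1], ["a", "b"])
        f2 = make_forest([t2], ["a", "b"])
        fsum = make_forest([t1, t2], ["a", "b"])
        phi1 = exact_shap(f1, x, bg).phi.to_numpy()
        phi2 = exact_shap(f2, x, bg).phi.to_numpy()
        phis = exact_shap(fsum, x, bg).phi.to_numpy()
        np.testing.assert_allclose(phis, phi1 + phi2, atol=1e-10)


class TestSummaries:
    def matrix_from(self, phi_rows, base, preds, names=("a", "b")):
        from epiloop.shapley import ShapMatrix
        df = pd.DataFrame(phi_rows, columns=list(names))
        df.insert(0, "transcript_id", [f"t{i}" for i in range(len(df))])
        df["base_value"] = base
        df["prediction"] = preds
        return ShapMatrix(df=df, feature_names=list(names))

    def test_direction_stratified_mean_abs(self):
        sm = self.matrix_from([[1.0, -2.0], [3.0, 0.0]], 0.0, [1.0, 2.0])
        out = mean_abs_shap_by_direction(sm)
        up = out[out.stratum == "up"].set_index("feature")
        assert up.loc["a", "mean_abs"] == pytest.approx(2.0)
        assert up.loc["b", "mean_abs"] == pytest.approx(1.0)
        assert (out.stratum == "down").sum() == 0   # empty stratum absent

    def test_dependence_pairs_aligned(self, small_forest, default_table):
        X = default_table.X()[:30]
        bg = sample_background(default_table.X(), 32, seed=1)
        sm = shap_matrix(small_forest, X, bg)
        data = dependence_data(sm, X, "ATAC")
        assert len(data["pairs"]) == 30
        np.testing.assert_array_equal(
            data["pairs"]["feature_value"].to_numpy(),
            X[:, default_table.feature_names.index("ATAC")])
        with pytest.raises(ValueError, match="unknown feature"):
            dependence_data(sm, X, "H3K0me0")

    def test_monotone_stump_gives_monotone_phi(self):
        forest = make_forest([stump(0, 0.0, -1.0, 1.0)], ["a"])
        bg = np.array([[-2.0], [2.0]])
        xs = np.array([[-1.0], [1.0]])
        sm = shap_matrix(forest, xs, bg)
        phi = sm.phi()[:, 0]
        assert phi[0] <= phi[1]

    def test_waterfall_runs_base_to_prediction(self, small_forest,
                                               default_table):
        X = default_table.X()
        bg = sample_background(X, 32, seed=1)
        sm = shap_matrix(small_forest, X[:5], bg)
        for i in range(5):
            expl = sm.row(i)
            wf = waterfall(expl)
            assert (np.diff(np.abs(wf["phi"].to_numpy())) <= 1e-12).all()
            assert wf["cumulative"].iloc[-1] == pytest.approx(
                expl.prediction, abs=1e-8)

    def test_flat_waterfall_for_zero_phi(self):
        from epiloop.shapley import ShapExplanation
        expl = ShapExplanation("t", 1.5, pd.Series([0.0, 0.0],
                                                   index=["a", "b"]), 1.5)
        wf = waterfall(expl)
        assert (wf["cumulative"] == 1.5).all()
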