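import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qrfdrug import (
    Dataset,
    Forest,
    GeneratorSpec,
    PredictionInterval,
    QuantileRegressionForest,
    conditional_cdf,
    fit_forest,
    fit_tree,
    forest_weights,
    generate,
    oob_predict,
    predict_mean,
    predict_quantile,
    prediction_interval,
    tree_weights,
)
from qrfdrug.qrf import oob_weights, weighted_quantiles

from brute import brute_forest_weights, brute_quantile, brute_tree_weights


def _single_leaf_tree(y, bootstrap):
    """A tree guaranteed to be one leaf (min_node > n), with a chosen bootstrap."""
    y = np.asarray(y, dtype=float)
    n = y.size
    data = Dataset(
        np.zeros((n, 1)), y, [f"s{i}" for i in range(n)], ["f0"]
    )
    return data, fit_tree(
        data, np.asarray(bootstrap), m=1, min_node=n + 1, rng=np.random.default_rng(0)
    )


class TestTreeWeights:
    def test_single_leaf_uniform(self):
        data, tree = _single_leaf_tree([1.0, 2.0, 3.0], [0, 1, 2])
        w = tree_weights(tree, np.array([0.0]), 3)
        assert np.allclose(w, [1 / 3, 1 / 3, 1 / 3])

    def test_bootstrap_multiplicity(self):
        # leaf holding sample a twice and b once -> weights 2/3, 1/3
        data, tree = _single_leaf_tree([1.0, 2.0, 3.0], [0, 0, 1])
        w = tree_weights(tree, np.array([0.0]), 3)
        assert np.allclose(w, [2 / 3, 1 / 3, 0.0])

    def test_matches_brute_force_on_random_queries(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        rng = np.random.default_rng(12)
        tree = skewed_forest.trees[1]
        for _ in range(50):
            x = rng.normal(size=data.M)
            assert np.allclose(
                tree_weights(tree, x, data.n),
                brute_tree_weights(tree, x, data.X),
                atol=1e-12,
            )


class TestForestWeights:
    def test_sum_to_one_over_random_queries(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        rng = np.random.default_rng(13)
        for _ in range(100):
            w = forest_weights(skewed_forest, rng.normal(size=data.M))
            assert w.min() >= 0
            assert abs(w.sum() - 1.0) <= 1e-9

    def test_matches_brute_force(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        rng = np.random.default_rng(14)
        for _ in range(5):
            x = rng.normal(size=data.M)
            assert np.allclose(
                forest_weights(skewed_forest, x),
                brute_forest_weights(skewed_forest, x),
                atol=1e-12,
            )


class TestQuantilePrediction:
    def test_inf_definition_on_uniform_weights(self):
        data, tree = _single_leaf_tree([1.0, 2.0, 3.0, 4.0], [0, 1, 2, 3])
        forest = Forest(trees=[tree], data=data, T=1, m=1, min_node=data.n + 1, seed=0)
        x = np.array([0.0])
        assert predict_quantile(forest, x, 0.5) == 2.0  # F(2) = 0.5 >= 0.5
        assert predict_quantile(forest, x, 0.25) == 1.0
        assert predict_quantile(forest, x, 0.51) == 3.0

    def test_two_point_distribution(self):
        data, tree = _single_leaf_tree([0.0, 10.0], [0, 1])
        forest = Forest(trees=[tree], data=data, T=1, m=1, min_node=data.n + 1, seed=0)
        x = np.array([0.0])
        assert predict_quantile(forest, x, 0.25) == 0.0
        assert predict_quantile(forest, x, 0.75) == 10.0

    def test_agrees_with_brute_scan(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        rng = np.random.default_rng(15)
        for _ in range(100):
            x = rng.normal(size=data.M)
            tau = rng.uniform(0.01, 0.99)
            w = forest_weights(skewed_forest, x)
            assert predict_quantile(skewed_forest, x, tau) == brute_quantile(
                data.y, w, tau
            )

    def test_monotone_in_tau_and_within_range(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        rng = np.random.default_rng(16)
        taus = [0.025, 0.1, 0.25, 0.5, 0.75, 0.9, 0.975]
        for _ in range(20):
            q = predict_quantile(skewed_forest, rng.normal(size=data.M), taus)
            assert (np.diff(q) >= 0).all()
            assert q[0] >= data.y.min() and q[-1] <= data.y.max()

    def test_invalid_tau_rejected(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        for tau in (0.0, 1.0, -0.1, 1.7):
            with pytest.raises(ValueError, match="tau"):
                predict_quantile(skewed_forest, data.X[0], tau)


class TestMeanPrediction:
    def test_uniform_weights_average(self):
        data, tree = _single_leaf_tree([1.0, 2.0, 3.0, 4.0], [0, 1, 2, 3])
        forest = Forest(trees=[tree], data=data, T=1, m=1, min_node=data.n + 1, seed=0)
        assert predict_mean(forest, np.array([0.0])) == pytest.approx(2.5)

    def test_concentrated_weights(self):
        data, tree = _single_leaf_tree([1.0, 5.0], [1, 1])
        forest = Forest(trees=[tree], data=data, T=1, m=1, min_node=data.n + 1, seed=0)
        assert predict_mean(forest, np.array([0.0])) == 5.0

    def test_mean_within_training_range(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        rng = np.random.default_rng(17)
        for _ in range(50):
            m = predict_mean(skewed_forest, rng.normal(size=data.M))
            assert data.y.min() <= m <= data.y.max()


class TestConditionalCDF:
    def test_valid_distribution_function(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        cdf = conditional_cdf(skewed_forest, data.X[5])
        assert (np.diff(cdf.cdf) >= -1e-12).all()
        assert cdf.cdf[-1] == 1.0
        assert cdf.evaluate(data.y.min() - 1) == 0.0
        assert cdf.evaluate(data.y.max()) == 1.0

    def test_quantile_inverts_cdf(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        cdf = conditional_cdf(skewed_forest, data.X[5])
        for tau in (0.1, 0.5, 0.9):
            q = cdf.quantile(tau)
            assert cdf.evaluate(q) >= tau - 1e-9
            assert q == predict_quantile(skewed_forest, data.X[5], tau)


class TestPredictionInterval:
    def test_discrete_uniform_percentiles(self):
        y = np.arange(1.0, 101.0)
        data, tree = _single_leaf_tree(y, np.arange(100))
        forest = Forest(trees=[tree], data=data, T=1, m=1, min_node=data.n + 1, seed=0)
        iv = prediction_interval(forest, np.array([0.0]), alpha=0.05)
        assert (iv.lower, iv.upper) == (3.0, 98.0)  # inf definition on the grid
        assert iv.length == 95.0

    def test_nesting_in_alpha(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        x = data.X[7]
        wide = prediction_interval(skewed_forest, x, alpha=0.05)
        narrow = prediction_interval(skewed_forest, x, alpha=0.4)
        assert wide.lower <= narrow.lower <= narrow.upper <= wide.upper

    def test_constant_response_zero_length(self):
        rng = np.random.default_rng(18)
        data = Dataset(
            rng.normal(size=(15, 2)), np.full(15, 3.3),
            [f"s{i}" for i in range(15)], ["a", "b"],
        )
        forest = fit_forest(data, T=5, seed=0)
        iv = prediction_interval(forest, data.X[0], alpha=0.05)
        assert iv.length == 0.0 and iv.lower == 3.3

    def test_alpha_validation(self, skewed_forest, skewed_panel):
        data, _ = skewed_panel
        with pytest.raises(ValueError, match="alpha"):
            prediction_interval(skewed_forest, data.X[0], alpha=1.5)
        with pytest.raises(ValueError):
            PredictionInterval(lower=1.0, upper=0.0, alpha=0.05)


class TestOOBPrediction:
    def test_single_tree_inbag_samples_get_sentinel(self, skewed_panel):
        data, _ = skewed_panel
        forest = fit_forest(data, T=1, seed=21)
        with pytest.warns(UserWarning, match="in-bag in every tree"):
            oob = oob_predict(forest, taus=[0.5])
        tree = forest.trees[0]
        inbag = np.setdiff1d(np.arange(data.n), tree.oob_indices)
        assert oob["q0.5"].iloc[inbag].isna().all()
        assert oob["q0.5"].iloc[tree.oob_indices].notna().all()

    def test_own_weight_is_zero(self, skewed_panel):
        data, _ = skewed_panel
        forest = fit_forest(data, T=30, seed=22)
        W, counts = oob_weights(forest)
        assert (counts > 0).all()
        assert np.allclose(np.diag(W), 0.0, atol=1e-15)

    def test_oob_matches_cross_validation(self):
        # OOB prediction ~ k-fold CV prediction when T is large
        data, _ = generate(
            GeneratorSpec(n=200, M=10, s=3, noise_family="gaussian",
                          heteroscedastic=False, sigma=0.5, seed=23)
        )
        forest = fit_forest(data, T=500, seed=23)
        oob = oob_predict(forest, taus=[0.5]).to_numpy()[:, 0]

        cv = np.empty(data.n)
        folds = np.arange(data.n) % 5
        for k in range(5):
            train = Dataset(
                data.X[folds != k], data.y[folds != k],
                [s for s, f in zip(data.sample_ids, folds) if f != k],
                data.feature_ids,
            )
            fold_forest = fit_forest(train, T=500, seed=100 + k)
            for i in np.nonzero(folds == k)[0]:
                cv[i] = predict_mean(fold_forest, data.X[i])
        assert np.corrcoef(oob, cv)[0, 1] > 0.95


class TestConsistency:
    def test_median_error_decreases_with_sample_size(self):
        maes = []
        for n in (100, 400, 1600):
            data, truth = generate(
                GeneratorSpec(n=n, M=5, s=1, noise_family="gaussian",
                              heteroscedastic=False, sigma=0.5, seed=31)
            )
            forest = fit_forest(data, T=200, seed=31)
            q50 = oob_predict(forest, taus=[0.5], include_mean=False).to_numpy()[:, 0]
            true_med = truth.conditional_mean(data.X)
            ok = np.isfinite(q50)
            maes.append(np.mean(np.abs(q50[ok] - true_med[ok])))
        assert maes[2] < maes[0]


class TestWeightedQuantiles:
    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=20),
        st.integers(0, 2**31 - 1),
    )
    def test_monotone_and_in_range_for_random_weights(self, ys, seed):
        y = np.asarray(ys, dtype=float)
        rng = np.random.default_rng(seed)
        w = rng.dirichlet(np.ones(y.size))
        taus = np.sort(rng.uniform(0.01, 0.99, size=5))
        q = weighted_quantiles(y, w[None, :], taus)[0]
        assert (np.diff(q) >= 0).all()
        assert q[0] >= y.min() and q[-1] <= y.max()


class TestModelFrontEnd:
    def test_from_dataset_round_trip(self, skewed_panel):
        data, _ = skewed_panel
        res = QuantileRegressionForest.from_dataset(data, n_trees=20).fit(seed=1)
        x = data.X[:3]
        assert np.allclose(
            res.predict_mean(x), [predict_mean(res.forest, xi) for xi in x]
        )
        ivs = res.prediction_intervals(x, alpha=0.1)
        assert (ivs["length"] >= 0).all()
        assert "Quantile Regression Forest Results" in res.summary()

    def test_oob_accuracy_positive_on_signal(self, skewed_panel):
        data, _ = skewed_panel
        res = QuantileRegressionForest.from_dataset(data, n_trees=80).fit(seed=2)
        assert res.oob_accuracy("mean") > 0.3
        assert res.oob_accuracy("median") > 0.3
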