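"""Boosted regression trees: learner mechanics, AUC, influence,
interactions, determinism. Heavier niche-recovery benchmarks live in the
acceptance suite."""

import numpy as np
import pandas as pd
import pytest

from fairycircles.brt import (
    BRTConfig,
    auc,
    cv_auc,
    fit_brt,
    pairwise_interaction,
    partial_dependence,
    predict_grid,
    relative_influence,
    simplify,
)

FAST = dict(learning_rate=0.05, n_trees=80, tree_complexity=4, min_samples_leaf=5)


@pytest.fixture
def threshold_data(rng):
    """Separable rule y = 1[x1 > 0] with one nuisance covariate."""
    X = pd.DataFrame({"x1": rng.normal(0, 1, 500), "x2": rng.normal(0, 1, 500)})
    y = (X["x1"] > 0).astype(int).to_numpy()
    return X, y


class TestAuc:
    def test_perfect_scores(self):
        assert auc([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_anti_ranked_scores(self):
        assert auc([3, 2, 1, 0], [0, 0, 1, 1]) == 0.0

    def test_all_ties_half_credit(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.9], [1, 1])


class TestFitBrt:
    def test_separable_rule_reaches_training_auc_one(self, threshold_data):
        X, y = threshold_data
        cfg = BRTConfig(**FAST, bag_fraction=1.0, seed=0)
        model = fit_brt(X, y, cfg)  # lr * n_trees = 4 > 3
        assert auc(model.predict_proba(X), y) == 1.0

    def test_full_bag_deviance_monotone_nonincreasing(self, threshold_data):
        X, y = threshold_data
        cfg = BRTConfig(**FAST, bag_fraction=1.0, seed=0)
        model = fit_brt(X, y, cfg)
        trace = model.deviance_trace
        assert np.all(np.diff(trace) <= 1e-12)

    def test_tree_split_budget_respected(self, threshold_data):
        X, y = threshold_data
        cfg = BRTConfig(**FAST, seed=0)
        model = fit_brt(X, y, cfg)
        assert all(t.n_splits <= cfg.tree_complexity for t in model.trees)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError):
            fit_brt(X, np.ones(50), BRTConfig(**FAST))

    def test_seeded_determinism(self, threshold_data):
        X, y = threshold_data
        cfg = BRTConfig(**FAST, seed=7)
        a = fit_brt(X, y, cfg).predict_proba(X)
        b = fit_brt(X, y, cfg).predict_proba(X)
        np.testing.assert_array_equal(a, b)

    def test_probabilities_bounded(self, threshold_data):
        X, y = threshold_data
        p = fit_brt(X, y, BRTConfig(**FAST, seed=1)).predict_proba(X)
        assert p.min() >= 0.0 and p.max() <= 1.0


class TestCvAuc:
    def test_no_signal_gives_chance_auc(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        y = rng.integers(0, 2, 300)
        cfg = BRTConfig(**FAST, cv_folds=5, seed=0)
        res = cv_auc(X, y, cfg)
        assert res["auc_mean"] == pytest.approx(0.5, abs=0.08)

    def test_separable_signal_scores_high(self, threshold_data):
        X, y = threshold_data
        cfg = BRTConfig(**FAST, cv_folds=5, seed=0)
        assert cv_auc(X, y, cfg)["auc_mean"] >= 0.95


class TestRelativeInfluence:
    def test_single_predictor_takes_everything(self, rng):
        X = pd.DataFrame({"only": rng.normal(0, 1, 300)})
        y = (X["only"] > 0).astype(int).to_numpy()
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        infl = relative_influence(model)
        assert infl["only"] == pytest.approx(100.0)

    def test_normalization_to_hundred(self, threshold_data):
        X, y = threshold_data
        infl = relative_influence(fit_brt(X, y, BRTConfig(**FAST, seed=0)))
        assert infl.sum() == pytest.approx(100.0, abs=1e-6)
        assert (infl >= 0).all()


class TestSimplify:
    def test_single_predictor_returned_unchanged(self, rng):
        X = pd.DataFrame({"only": rng.normal(0, 1, 200)})
        y = (X["only"] > 0).astype(int).to_numpy()
        res = simplify(X, y, BRTConfig(**FAST, cv_folds=4, seed=0))
        assert res["variables"] == ["only"]

    def test_pure_noise_predictor_dropped(self, rng):
        X = pd.DataFrame(
            {"signal": rng.normal(0, 1, 400), "junk": rng.normal(0, 1, 400)}
        )
        y = (X["signal"] > 0).astype(int).to_numpy()
        res = simplify(X, y, BRTConfig(**FAST, cv_folds=4, seed=0))
        assert res["variables"] == ["signal"]

    def test_seeded_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 3)), columns=["a", "b", "c"])
        y = (X["a"] + 0.2 * X["b"] > 0).astype(int).to_numpy()
        cfg = BRTConfig(**FAST, cv_folds=4, seed=3)
        assert simplify(X, y, cfg)["variables"] == simplify(X, y, cfg)["variables"]


class TestPartialDependence:
    def test_absent_variable_gives_constant_curve(self, rng):
        X = pd.DataFrame({"used": rng.normal(0, 1, 300), "unused": np.zeros(300)})
        y = (X["used"] > 0).astype(int).to_numpy()
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        curve = partial_dependence(model, "unused", np.linspace(-2, 2, 9))
        assert curve["link"].nunique() == 1

    def test_threshold_model_curve_increases(self, threshold_data):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        curve = partial_dependence(model, "x1", np.linspace(-2, 2, 21))
        assert curve["link"].iloc[-1] > curve["link"].iloc[0]
        assert (np.diff(curve["link"]) >= -1e-9).all()

    def test_single_point_grid(self, threshold_data):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        assert len(partial_dependence(model, "x1", [0.3])) == 1

    def test_unknown_variable_rejected(self, threshold_data):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        with pytest.raises(KeyError):
            partial_dependence(model, "nope", [0.0])


class TestPairwiseInteraction:
    def test_symmetry(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        y = ((X["a"] * X["b"]) > 0).astype(int).to_numpy()
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        ab = pairwise_interaction(model, X, ("a", "b"))
        ba = pairwise_interaction(model, X, ("b", "a"))
        assert ab == pytest.approx(ba, rel=1e-9)

    def test_stumps_are_additive(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 2)), columns=["a", "b"])
        y = ((X["a"] * X["b"]) > 0).astype(int).to_numpy()
        cfg = BRTConfig(
            learning_rate=0.05, n_trees=80, tree_complexity=1, min_samples_leaf=5, seed=0
        )
        model = fit_brt(X, y, cfg)
        assert pairwise_interaction(model, X, ("a", "b")) == pytest.approx(0.0, abs=1e-9)

    def test_multiplicative_beats_additive(self, rng):
        """Additive log-odds surface vs a multiplicative one of equal
        marginal strength: the non-additive residual must be far smaller."""
        n = 1500
        X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        p_add = 1 / (1 + np.exp(-1.5 * (X["a"] + X["b"])))
        p_mult = 1 / (1 + np.exp(-3.0 * X["a"] * X["b"]))
        y_add = (rng.uniform(size=n) < p_add).astype(int)
        y_mult = (rng.uniform(size=n) < p_mult).astype(int)
        # enough boosting rounds that the additive surface is well fit;
        # underfit ensembles show spurious interaction from bagging noise
        cfg = BRTConfig(
            learning_rate=0.05, n_trees=200, tree_complexity=4,
            min_samples_leaf=5, seed=0,
        )
        size_add = pairwise_interaction(fit_brt(X, y_add, cfg), X, ("a", "b"))
        size_mult = pairwise_interaction(fit_brt(X, y_mult, cfg), X, ("a", "b"))
        assert size_add < 0.05 * size_mult

    def test_identical_pair_rejected(self, threshold_data):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        with pytest.raises(ValueError):
            pairwise_interaction(model, X, ("x1", "x1"))


class TestPredictGrid:
    def test_constant_layers_give_constant_raster(self, threshold_data):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        grids = {"x1": np.full((5, 7), 0.8), "x2": np.zeros((5, 7))}
        out = predict_grid(model, grids)
        assert out.shape == (5, 7)
        assert np.ptp(out) == 0.0
        point = model.predict_proba(pd.DataFrame({"x1": [0.8], "x2": [0.0]}))[0]
        assert out[0, 0] == pytest.approx(point)

    def test_output_is_probability(self, threshold_data, rng):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        grids = {"x1": rng.normal(size=(6, 6)), "x2": rng.normal(size=(6, 6))}
        out = predict_grid(model, grids)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_missing_layer_rejected(self, threshold_data):
        X, y = threshold_data
        model = fit_brt(X, y, BRTConfig(**FAST, seed=0))
        with pytest.raises(KeyError):
            predict_grid(model, {"x1": np.zeros((3, 3))})
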