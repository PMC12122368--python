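"""Boosted-tree engine: fitting contracts, tree selection, influence, PD."""

import numpy as np
import pandas as pd
import pytest

from reefrestore import brt_engine as be


def make_classification(n=300, seed=0, signal=2.0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "a": rng.standard_normal(n),
        "b": rng.standard_normal(n),
        "c": rng.standard_normal(n),
    })
    logit = signal * X["a"].to_numpy()
    y = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    return X, y.astype(int)


@pytest.fixture()
def small_cfg():
    return be.BRTConfig(learning_rate=0.1, bag_fraction=0.5, tree_complexity=2,
                        n_trees_range=(20, 120), n_trees_step=10, n_folds=3,
                        loss="bernoulli")


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"learning_rate": 0.0}, {"bag_fraction": 1.5},
        {"tree_complexity": 0}, {"loss": "poisson"},
        {"n_trees_range": (100, 50)},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            be.BRTConfig(**kw)

    def test_degenerate_grid_two_candidates(self):
        cfg = be.BRTConfig(n_trees_range=(50, 10000), n_trees_step=9950)
        assert list(cfg.tree_grid()) == [50, 10000]


class TestFitContracts:
    def test_probability_outputs_in_unit_interval(self, small_cfg):
        X, y = make_classification()
        model = be.fit_brt(X, y, small_cfg, n_trees=60)
        p = model.predict(X)
        assert np.all((p >= 0) & (p <= 1))

    def test_deterministic_under_seed(self, small_cfg):
        X, y = make_classification()
        p1 = be.fit_brt(X, y, small_cfg, n_trees=60).predict(X)
        p2 = be.fit_brt(X, y, small_cfg, n_trees=60).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_response_rejected(self, small_cfg):
        X, _ = make_classification()
        with pytest.raises(ValueError):
            be.fit_brt(X, np.ones(len(X), dtype=int), small_cfg, n_trees=50)

    def test_missing_values_rejected(self, small_cfg):
        X, y = make_classification()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            be.fit_brt(X, y, small_cfg, n_trees=50)

    def test_staged_prediction_consistency(self, small_cfg):
        # a refit truncated at n trees equals the staged prediction at n
        X, y = make_classification()
        long = be.fit_brt(X, y, small_cfg, n_trees=100)
        short = be.fit_brt(X, y, small_cfg, n_trees=40)
        staged = None
        for i, stage in enumerate(long.estimator.staged_predict_proba(X), start=1):
            if i == 40:
                staged = stage[:, 1]
                break
        np.testing.assert_allclose(staged, short.predict(X), rtol=1e-10)

    def test_weights_match_row_duplication(self):
        # with no row subsampling, doubling a row's weight must equal
        # duplicating the row
        X, y = make_classification(n=120, seed=3)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=1.0, tree_complexity=2,
                           loss="bernoulli")
        w = np.ones(len(X))
        w[y == 1] = 2.0
        weighted = be.fit_brt(X, y, cfg, sample_weight=w, n_trees=50)
        X_dup = pd.concat([X, X[y == 1]], ignore_index=True)
        y_dup = np.concatenate([y, y[y == 1]])
        duplicated = be.fit_brt(X_dup, y_dup, cfg, n_trees=50)
        assert np.mean(np.abs(weighted.predict(X) - duplicated.predict(X))) < 0.02


class TestTreeSelection:
    def test_learnable_signal_elbow(self):
        X, y = make_classification(n=400, seed=1, signal=3.0)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=0.8, tree_complexity=2,
                           n_trees_range=(10, 300), n_trees_step=10, n_folds=3,
                           loss="bernoulli")
        n_trees, trace = be.select_n_trees(X, y, cfg)
        assert n_trees < 300
        # deviance decreases from the start of the trace to its minimum
        assert trace.deviance.iloc[0] > trace.deviance.min()

    def test_pure_noise_selects_near_minimum(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((300, 3)), columns=list("abc"))
        y = rng.integers(0, 2, 300)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=0.8, tree_complexity=2,
                           n_trees_range=(10, 200), n_trees_step=10, n_folds=3,
                           loss="bernoulli")
        n_trees, _ = be.select_n_trees(X, y, cfg)
        assert n_trees <= 40

    def test_ties_take_smallest_count(self):
        # constant response in regression: deviance flat, smallest wins
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((60, 2)), columns=list("ab"))
        y = np.zeros(60)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=1.0, tree_complexity=1,
                           n_trees_range=(10, 50), n_trees_step=10, n_folds=3,
                           loss="squared")
        n_trees, trace = be.select_n_trees(X, y, cfg)
        assert n_trees == 10


class TestInfluence:
    def test_single_usable_predictor_takes_all(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.standard_normal(200),
                          "b": np.zeros(200)})  # constant: never split on
        y = (X["a"] > 0).astype(int)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=1.0, tree_complexity=1,
                           loss="bernoulli")
        model = be.fit_brt(X, y, cfg, n_trees=30)
        infl = be.relative_influence(model)
        assert infl["a"] == pytest.approx(100.0, abs=1e-9)

    def test_influences_sum_to_100(self, small_cfg):
        X, y = make_classification()
        model = be.fit_brt(X, y, small_cfg, n_trees=60)
        infl = be.relative_influence(model)
        assert infl.sum() == pytest.approx(100.0, abs=1e-6)
        assert (infl >= 0).all()

    def test_planted_effect_ratio_orders_influence(self):
        # effects 3:1 on two predictors; majority of seeded fits must
        # rank them accordingly
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            X = pd.DataFrame({"strong": rng.standard_normal(300),
                              "weak": rng.standard_normal(300),
                              "noise": rng.standard_normal(300)})
            y = (3.0 * X["strong"] + 1.0 * X["weak"]
                 + rng.standard_normal(300)).to_numpy()
            cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=0.7,
                               tree_complexity=2, loss="squared", seed=s)
            model = be.fit_brt(X, y, cfg, n_trees=80)
            infl = be.relative_influence(model)
            wins += infl["strong"] > infl["weak"] > infl["noise"]
        assert wins >= 6


class TestPartialDependence:
    def test_constant_feature_gives_flat_curve(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.standard_normal(200), "b": np.zeros(200)})
        y = (X["a"] > 0).astype(int)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=1.0, tree_complexity=1,
                           loss="bernoulli")
        model = be.fit_brt(X, y, cfg, n_trees=30)
        curve = be.partial_dependence(model, "b", grid_size=20)
        assert curve.yhat.max() - curve.yhat.min() < 1e-6

    def test_monotone_planted_effect(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.standard_normal(300),
                          "b": rng.standard_normal(300)})
        y = X["a"].to_numpy() + 0.1 * rng.standard_normal(300)
        cfg = be.BRTConfig(learning_rate=0.1, bag_fraction=0.7, tree_complexity=2,
                           loss="squared")
        model = be.fit_brt(X, y, cfg, n_trees=100)
        curve = be.partial_dependence(model, "a", grid_size=30)
        from scipy.stats import spearmanr
        assert spearmanr(curve.value, curve.yhat).statistic > 0.9

    def test_matches_row_loop_oracle(self, small_cfg):
        X, y = make_classification(n=100)
        model = be.fit_brt(X, y, small_cfg, n_trees=40)
        curve = be.partial_dependence(model, "a", grid_size=7)
        for _, row in curve.iterrows():
            preds = []
            for i in range(len(X)):
                xi = X.iloc[[i]].copy()
                xi["a"] = row.value
                preds.append(model.predict(xi)[0])
            assert row.yhat == pytest.approx(np.mean(preds), rel=1e-10)

    def test_unknown_variable_rejected(self, small_cfg):
        X, y = make_classification(n=100)
        model = be.fit_brt(X, y, small_cfg, n_trees=20)
        with pytest.raises(KeyError):
            be.partial_dependence(model, "zzz")
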