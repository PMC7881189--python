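"""Random-forest ABC: votes, posterior probability, quantile estimation.

These tests drive the forests with synthetic gaussian reference tables so
the planted truth (class separation, parameter maps) is known exactly.
"""

import numpy as np
import pandas as pd
import pytest

from bridgehead import choose_model, estimate_parameter
from bridgehead.abcrf import QuantileRegressionForest, classify_observed, fit_choice_forest
from bridgehead.simulate import ReferenceTable

from conftest import gaussian_table


class TestChooseModel:
    def test_votes_sum_to_forest_size(self, rng):
        tbl = gaussian_table(rng, 60, 5, {"A": 0.0, "B": 0.5})
        res = choose_model(tbl, np.zeros(5), n_trees=201, seed=1)
        assert sum(res.votes.values()) == 201
        assert res.selected in ("A", "B")
        assert 0.0 <= res.posterior_probability <= 1.0

    def test_separable_classes_recovered_with_confidence(self, rng):
        # planted mean shift of 10 pooled standard deviations
        tbl = gaussian_table(rng, 150, 6, {"near": 0.0, "far": 10.0})
        obs = rng.normal(0.0, 1.0, size=6)
        res = choose_model(tbl, obs, n_trees=500, seed=2)
        assert res.selected == "near"
        assert res.votes["near"] > 0.9 * 500
        assert res.posterior_probability > 0.9
        assert res.prior_error_rate < 0.05

    def test_indistinguishable_generators_split_votes(self, rng):
        # both labels draw from the same distribution: votes hover at 50%
        # and the out-of-bag error is that of a coin flip
        tbl = gaussian_table(rng, 250, 6, {"A": 0.0, "B": 0.0})
        forest = fit_choice_forest(tbl, n_trees=200, seed=3)
        shares = []
        for _ in range(100):
            obs = rng.normal(0.0, 1.0, size=6)
            res = classify_observed(forest, tbl, obs)
            shares.append(res.votes["A"] / res.n_trees)
        assert np.mean(shares) == pytest.approx(0.5, abs=0.05)
        assert forest["prior_error"] == pytest.approx(0.5, abs=0.1)

    def test_deterministic_per_seed(self, rng):
        tbl = gaussian_table(rng, 80, 4, {"A": 0.0, "B": 1.0})
        obs = np.full(4, 0.2)
        r1 = choose_model(tbl, obs, n_trees=100, seed=7)
        r2 = choose_model(tbl, obs, n_trees=100, seed=7)
        assert r1 == r2

    def test_single_label_rejected(self, rng):
        tbl = gaussian_table(rng, 30, 4, {"A": 0.0})
        with pytest.raises(ValueError, match=">= 2 scenario labels"):
            choose_model(tbl, np.zeros(4), n_trees=50, seed=1)

    def test_non_conformable_observed_rejected(self, rng):
        tbl = gaussian_table(rng, 30, 4, {"A": 0.0, "B": 1.0})
        with pytest.raises(ValueError, match="statistics"):
            choose_model(tbl, np.zeros(7), n_trees=50, seed=1)

    def test_optional_lda_axes_keep_contract(self, rng):
        tbl = gaussian_table(rng, 80, 5, {"A": 0.0, "B": 3.0})
        obs = rng.normal(0.0, 1.0, size=5)
        res = choose_model(tbl, obs, n_trees=100, seed=4, add_lda_axes=True)
        assert sum(res.votes.values()) == 100
        assert res.selected == "A"

    def test_tie_breaks_to_lowest_label(self):
        from bridgehead.abcrf import ModelChoiceResult

        res = ModelChoiceResult(votes={"Sb": 50, "Sa": 50}, selected="Sa",
                                posterior_probability=0.5,
                                prior_error_rate=0.5, n_trees=100)
        assert res.selected == "Sa"
        with pytest.raises(ValueError, match="sum"):
            ModelChoiceResult(votes={"Sa": 10}, selected="Sa",
                              posterior_probability=0.5,
                              prior_error_rate=0.5, n_trees=100)


class TestEstimateParameter:
    def test_constant_response_degenerate_estimate(self, rng):
        tbl = gaussian_table(rng, 100, 4, {"A": 0.0},
                             param_fn=lambda s, r: 3.25)
        est = estimate_parameter(tbl, np.zeros(4), "theta", n_trees=100, seed=1)
        assert est.median == est.q025 == est.q975 == 3.25

    def test_quantile_ordering_always_holds(self, rng):
        tbl = gaussian_table(rng, 150, 4, {"A": 0.0},
                             param_fn=lambda s, r: r.uniform(0, 1))
        for k in range(10):
            est = estimate_parameter(tbl, rng.normal(0, 1, 4), "theta",
                                     n_trees=80, seed=k)
            assert est.q025 <= est.median <= est.q975

    def test_informative_statistic_recovers_parameter(self, rng):
        # theta drives the first statistic: s0 = theta + small noise
        def param_fn(stats, r):
            return stats[0] + r.normal(0, 0.05)

        tbl = gaussian_table(rng, 800, 4, {"A": 0.0}, param_fn=param_fn)
        obs = np.array([1.2, 0.0, 0.0, 0.0])
        est = estimate_parameter(tbl, obs, "theta", n_trees=300, seed=5)
        assert est.median == pytest.approx(1.2, abs=0.25)
        assert est.q025 < 1.2 < est.q975

    def test_requires_single_scenario_table(self, rng):
        tbl = gaussian_table(rng, 40, 4, {"A": 0.0, "B": 1.0},
                             param_fn=lambda s, r: 1.0)
        with pytest.raises(ValueError, match="one"):
            estimate_parameter(tbl, np.zeros(4), "theta", n_trees=50, seed=1)

    def test_unknown_parameter_rejected(self, rng):
        tbl = gaussian_table(rng, 40, 4, {"A": 0.0},
                             param_fn=lambda s, r: 1.0)
        with pytest.raises(KeyError, match="zz"):
            estimate_parameter(tbl, np.zeros(4), "zz", n_trees=50, seed=1)

    def test_deterministic_per_seed(self, rng):
        tbl = gaussian_table(rng, 120, 4, {"A": 0.0},
                             param_fn=lambda s, r: r.uniform(0, 10))
        obs = np.zeros(4)
        e1 = estimate_parameter(tbl, obs, "theta", n_trees=100, seed=11)
        e2 = estimate_parameter(tbl, obs, "theta", n_trees=100, seed=11)
        assert (e1.median, e1.q025, e1.q975) == (e2.median, e2.q025, e2.q975)


class TestQuantileForest:
    def test_weights_sum_to_one(self, rng):
        X = rng.normal(size=(200, 3))
        y = X[:, 0] + rng.normal(0, 0.1, 200)
        qrf = QuantileRegressionForest(n_trees=100, seed=0).fit(X, y)
        w = qrf.weights(np.array([0.5, 0.0, 0.0]))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()

    def test_monotone_information_more_rows_do_not_hurt(self, rng):
        """Doubling the reference table must not worsen out-of-bag error
        beyond noise (paired over seeds)."""
        from sklearn.ensemble import RandomForestRegressor

        def oob_mse(n_rows, seed):
            r = np.random.default_rng(seed)
            X = r.normal(size=(n_rows, 4))
            y = X[:, 0] + 0.5 * X[:, 1] + r.normal(0, 0.3, n_rows)
            f = RandomForestRegressor(n_estimators=150, oob_score=True,
                                      random_state=seed, n_jobs=1).fit(X, y)
            return np.mean((f.oob_prediction_ - y) ** 2)

        diffs = [oob_mse(300, s) - oob_mse(600, s) for s in range(20)]
        # small tables may fluctuate, but on average more data helps
        assert np.mean(diffs) > -0.02
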