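"""Association models: oracles, error handling, joint effects."""

import numpy as np
import pandas as pd
import pytest

import swedgi as sg
from swedgi.models import ModelSpec


def expand_2x2(a, b, c, d):
    """Participant-level rows from a 2x2 (exposed/unexposed x case/control)."""
    rows = (
        [(1, 1)] * a + [(1, 0)] * b + [(0, 1)] * c + [(0, 0)] * d
    )
    return pd.DataFrame(rows, columns=["x", "y"])


class TestLogisticOracle:
    def test_or_equals_cross_product_ratio(self):
        a, b, c, d = 30, 20, 10, 40
        data = expand_2x2(a, b, c, d)
        res = sg.fit_logistic(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))
        assert res.estimate == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_null_2x2(self):
        data = expand_2x2(25, 25, 25, 25)
        res = sg.fit_logistic(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))
        assert res.estimate == pytest.approx(1.0, rel=1e-6)

    def test_nonbinary_outcome_rejected(self):
        data = pd.DataFrame({"x": [0, 1, 2], "y": [0.0, 0.5, 1.0]})
        with pytest.raises(ValueError, match="binary"):
            sg.fit_logistic(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))

    def test_separation_detected(self):
        data = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                             "y": np.r_[np.zeros(20), np.ones(20)]})
        with pytest.raises(RuntimeError, match="separation|converge"):
            sg.fit_logistic(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))


class TestLinearTrend:
    def test_outcome_equal_to_exposure(self):
        rng = np.random.default_rng(0)
        x = rng.integers(1, 6, 400).astype(float)
        data = pd.DataFrame({"x": x, "y": x})
        res = sg.fit_linear_trend(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))
        assert res.estimate == pytest.approx(1.0, abs=1e-10)
        assert res.p_trend < 1e-100

    def test_known_slope_with_noise(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 6, 2000).astype(float)
        y = 0.5 * x + rng.normal(0, 1, 2000)
        data = pd.DataFrame({"x": x, "y": y})
        res = sg.fit_linear_trend(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))
        assert abs(res.estimate - 0.5) < 2 * res.se
        assert res.ci95 == pytest.approx((res.estimate - 1.96 * res.se,
                                          res.estimate + 1.96 * res.se), abs=1e-3)

    def test_adjusted_means_linear_in_category(self):
        """With a perfectly linear category effect, indicator-coded adjusted
        means must be compatible with the continuous trend fit."""
        rng = np.random.default_rng(2)
        x = rng.integers(1, 6, 3000).astype(float)
        y = 4.0 + 0.1 * x + rng.normal(0, 0.3, 3000)
        data = pd.DataFrame({"x": x, "y": y})
        res = sg.fit_linear_trend(data, ModelSpec(outcome="y", exposure="x", covariate_tier="none"))
        means = res.extras["adjusted_means"]
        # without covariates the least-squares means are the raw category means
        raw = data.groupby("x")["y"].mean()
        for c, m in means.items():
            assert m == pytest.approx(raw[c], abs=1e-9)
        # slope of the means across categories reproduces the trend estimate
        slope_from_means = np.polyfit(sorted(means), [means[c] for c in sorted(means)], 1)[0]
        assert abs(slope_from_means - res.estimate) < 2 * res.se

    def test_rank_deficient_design_named(self):
        data = pd.DataFrame({"x": [1.0, 2, 3, 4], "x2": [2.0, 4, 6, 8], "y": [1.0, 2, 3, 4]})
        spec = ModelSpec(outcome="y", exposure="x", covariate_tier="none",
                         extra_covariates=["x2"])
        with pytest.raises(ValueError, match="x2"):
            sg.fit_linear_trend(data, spec)

    def test_missing_model_field_rejected(self):
        data = pd.DataFrame({"x": [1.0], "y": [1.0]})
        with pytest.raises(ValueError, match="age"):
            sg.fit_linear_trend(data, ModelSpec(outcome="y", exposure="x", covariate_tier="basic"))


class TestTiers:
    def test_tiers_are_nested(self):
        order = ["basic", "main", "main+BMI"]
        for small, big in zip(order, order[1:]):
            assert set(sg.TIERS[small]) <= set(sg.TIERS[big])

    def test_adding_covariates_never_increases_n(self, small_table):
        spec_main = ModelSpec(outcome="shannon", exposure="swedgi_category", covariate_tier="main")
        spec_basic = ModelSpec(outcome="shannon", exposure="swedgi_category", covariate_tier="basic")
        n_main = sg.fit_linear_trend(small_table, spec_main).n_used
        n_basic = sg.fit_linear_trend(small_table, spec_basic).n_used
        assert n_main <= n_basic


class TestInteraction:
    def test_self_interaction_rejected(self, small_table):
        spec = ModelSpec(outcome="mets", exposure="swedgi_category")
        with pytest.raises(ValueError, match="itself"):
            sg.test_interaction(small_table, spec, "swedgi_category", "swedgi_category")

    def test_collinear_product_rejected(self):
        data = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4],
                             "y": [0.2, 0.4, 0.1, 0.9]})
        # a is constant: a*b is collinear with b
        spec = ModelSpec(outcome="y", exposure="a", covariate_tier="none")
        with pytest.raises(ValueError, match="collinear|rank"):
            sg.test_interaction(data, spec, "a", "b")

    def test_strong_interaction_detected(self):
        rng = np.random.default_rng(3)
        n = 4000
        a = rng.integers(1, 4, n).astype(float)
        b = rng.integers(1, 4, n).astype(float)
        logit = -0.5 + 0.5 * (a - 2) * (b - 2)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        data = pd.DataFrame({"a": a, "b": b, "y": y})
        p = sg.test_interaction(data, ModelSpec(outcome="y", exposure="a", covariate_tier="none"), "a", "b")
        assert p < 1e-4


class TestMutualAdjustment:
    def test_independent_components_unchanged(self):
        rng = np.random.default_rng(4)
        n = 3000
        comps = {f"comp_{i}": rng.integers(0, 5, n).astype(float) for i in range(4)}
        y = 0.2 * comps["comp_0"] + rng.normal(0, 1, n)
        data = pd.DataFrame({**comps, "y": y})
        adj = sg.fit_mutually_adjusted_components(data, list(comps), "y", covariate_tier="none")
        solo = sg.fit_linear_trend(data, ModelSpec(outcome="y", exposure="comp_0", covariate_tier="none"))
        assert abs(adj["comp_0"].estimate - solo.estimate) < 2 * solo.se
        for k in ("comp_1", "comp_2", "comp_3"):
            assert abs(adj[k].estimate) < 3 * adj[k].se

    def test_collinear_components_rejected(self):
        data = pd.DataFrame({"comp_a": [1.0, 2, 3, 4], "comp_b": [2.0, 4, 6, 8],
                             "y": [1.0, 2, 1, 2]})
        with pytest.raises(ValueError, match="rank|collinear"):
            sg.fit_mutually_adjusted_components(data, ["comp_a", "comp_b"], "y",
                                                covariate_tier="none")


class TestJointEffect:
    @pytest.fixture(scope="class")
    def null_data(self):
        rng = np.random.default_rng(5)
        n = 3000
        return pd.DataFrame({
            "a": rng.normal(size=n),
            "b": rng.normal(size=n),
            "mets": (rng.random(n) < 0.3).astype(float),
        })

    def test_reference_cell_is_one(self, null_data):
        grids = sg.joint_effect(null_data, "a", "b", covariate_tier="none")
        assert grids["or_grid"].loc[1, 1] == 1.0

    def test_null_grid_near_one(self, null_data):
        grids = sg.joint_effect(null_data, "a", "b", covariate_tier="none")
        # CIs for null effects should cover 1 (allow one chance miss among 8)
        covered = ((grids["ci_low"] <= 1.0) & (grids["ci_high"] >= 1.0)).to_numpy().sum()
        assert covered >= 8

    def test_empty_cell_named(self):
        df = pd.DataFrame({
            "a": [1, 1, 2, 2, 3, 3] * 10,
            "b": [1, 2, 1, 2, 1, 2] * 10,
            "mets": ([0, 1] * 30),
        }).astype(float)
        # b has only 2 distinct values: tertile 3 of b never occurs with a=1
        with pytest.raises(ValueError):
            sg.joint_effect(df, "a", "b", covariate_tier="none", q=3, already_binned=True)

    def test_planted_marginal_effects_multiply(self):
        """Without interaction, the (high, high) OR is the product of the
        marginal ORs, up to sampling error."""
        rng = np.random.default_rng(6)
        n = 12000
        a = rng.integers(1, 4, n)
        b = rng.integers(1, 4, n)
        la, lb = np.log(0.8), np.log(0.7)
        logit = -0.5 + la * (a - 1) + lb * (b - 1)
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        df = pd.DataFrame({"a": a, "b": b, "mets": y})
        grids = sg.joint_effect(df, "a", "b", covariate_tier="none", q=3, already_binned=True)
        res = grids["result"]
        expected = 2 * la + 2 * lb
        est = np.log(grids["or_grid"].loc[3, 3])
        se = res.bse["cell_3_3"]
        assert abs(est - expected) < 2 * se
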