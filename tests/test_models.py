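"""Weighted logistic, random-intercept logistic and marginal effects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from hhnet.models import (
    RandomInterceptLogit,
    average_marginal_effect,
    fit_random_intercept_logistic,
    fit_weighted_logistic,
    run_association_suite,
    significance_stars,
)
import oracles


def _sim_frame(rng, n=1000, beta=0.5, intercept=-0.5, group_effects=None, n_groups=4):
    x = rng.normal(size=n)
    g = rng.integers(0, n_groups, size=n)
    eta = intercept + beta * x
    if group_effects is not None:
        eta = eta + np.asarray(group_effects)[g]
    y = (rng.random(n) < expit(eta)).astype(int)
    return pd.DataFrame(
        {
            "y": y,
            "x": x,
            "round": g.astype(str),
            "weight": rng.lognormal(0.0, 0.3, size=n),
            "cluster_id": rng.integers(0, 40, size=n),
        }
    )


class TestWeightedLogistic:
    def test_equal_weights_match_unweighted_fit(self):
        rng = np.random.default_rng(0)
        df = _sim_frame(rng).assign(weight=1.0)
        fit = fit_weighted_logistic(df, "y", "x")
        ref = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert fit.params["x"] == pytest.approx(ref.params["x"], abs=1e-8)
        assert fit.params["Intercept"] == pytest.approx(ref.params["const"], abs=1e-8)

    def test_weight_two_equals_duplicated_record(self):
        rng = np.random.default_rng(1)
        df = _sim_frame(rng, n=300)
        dup_idx = df.index[:50]
        weighted = df.copy()
        weighted.loc[dup_idx, "weight"] = 2.0
        weighted.loc[df.index.difference(dup_idx), "weight"] = 1.0
        duplicated = pd.concat([weighted, weighted.loc[dup_idx]], ignore_index=True)
        duplicated["weight"] = 1.0
        f1 = fit_weighted_logistic(weighted, "y", "x")
        f2 = fit_weighted_logistic(duplicated, "y", "x")
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-8)

    def test_listwise_deletion_is_counted(self):
        rng = np.random.default_rng(2)
        df = _sim_frame(rng, n=200)
        df.loc[:9, "x"] = np.nan
        fit = fit_weighted_logistic(df, "y", "x")
        assert fit.n == 190 and fit.n_dropped == 10

    def test_separation_is_flagged_not_fatal(self):
        df = pd.DataFrame(
            {
                "y": [0] * 20 + [1] * 20,
                "x": [0.0] * 20 + [1.0] * 20,  # perfect separation
                "weight": 1.0,
                "cluster_id": list(range(8)) * 5,
            }
        )
        fit = fit_weighted_logistic(df, "y", "x")
        assert "separation" in fit.flags

    def test_odds_ratio_is_exp_of_coefficient_and_ci_ordered(self):
        rng = np.random.default_rng(3)
        fit = fit_weighted_logistic(_sim_frame(rng), "y", "x")
        ors = fit.odds_ratios()
        assert ors.loc["x", "odds_ratio"] == pytest.approx(np.exp(fit.params["x"]))
        assert (ors["ci_low"] <= ors["odds_ratio"]).all()
        assert (ors["odds_ratio"] <= ors["ci_high"]).all()

    def test_type_one_error_of_wald_test_at_most_seven_percent(self):
        """Null simulations: the weighted, cluster-robust Wald test for the
        exposure rejects at ~5% (bounded at 7%)."""
        rng = np.random.default_rng(20)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            df = _sim_frame(rng, n=1500, beta=0.0, intercept=-0.3)
            df["cluster_id"] = np.repeat(np.arange(60), 25)
            fit = fit_weighted_logistic(df, "y", "x")
            p = fit.odds_ratios().loc["x", "p_value"]
            rejections += p < 0.05
        assert rejections / n_rep <= 0.07


class TestRandomInterceptLogit:
    def _fixture_90(self, seed=5):
        """3 rounds x 30 observations."""
        rng = np.random.default_rng(seed)
        block = pd.DataFrame({"x": rng.normal(size=30)})
        y = (rng.random(30) < expit(-0.3 + 0.6 * block["x"])).astype(int)
        X = sm.add_constant(block["x"]).to_numpy()
        groups = np.repeat([0, 1, 2], 30)
        return np.tile(y, 3), np.tile(X, (3, 1)), groups

    def test_loglike_matches_dense_grid_oracle(self):
        y, X, groups = self._fixture_90()
        model = RandomInterceptLogit(y, X, groups, n_points=15)
        for beta, sigma in [(np.array([-0.3, 0.6]), 0.4), (np.array([0.1, -0.2]), 0.8)]:
            got = model.loglike(np.r_[beta, np.log(sigma)])
            want = oracles.glmm_loglike_grid_oracle(y, X, groups, beta, sigma)
            assert got == pytest.approx(want, abs=1e-4)

    def test_identical_groups_drive_variance_to_boundary(self):
        y, X, groups = self._fixture_90()
        df = pd.DataFrame({"y": y, "x": X[:, 1], "round": groups.astype(str), "weight": 1.0})
        fit = fit_random_intercept_logistic(df, "y", "x")
        assert "variance_boundary" in fit.flags
        ref = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=0)
        assert fit.params["x"] == pytest.approx(ref.params["x"], abs=1e-3)
        assert fit.params["Intercept"] == pytest.approx(ref.params["const"], abs=1e-3)

    def test_single_group_rejected(self):
        df = pd.DataFrame({"y": [0, 1] * 20, "x": np.arange(40.0), "round": "2016", "weight": 1.0})
        with pytest.raises(ValueError, match="per.round|per-round"):
            fit_random_intercept_logistic(df, "y", "x")

    def test_recovers_random_intercept_sd(self):
        """Mean estimated SD over 200 replicates within 20% of the true 0.5
        (15 groups x 40 observations per replicate)."""
        rng = np.random.default_rng(11)
        true_sd, estimates = 0.5, []
        for _ in range(200):
            g = np.repeat(np.arange(15), 40)
            u = rng.normal(0.0, true_sd, size=15)[g]
            x = rng.normal(size=g.size)
            y = (rng.random(g.size) < expit(-0.2 + 0.4 * x + u)).astype(int)
            model = RandomInterceptLogit(y, sm.add_constant(x), g, n_points=11)
            res = model.fit()
            estimates.append(np.exp(res.x[-1]))
        assert np.mean(estimates) == pytest.approx(true_sd, rel=0.2)

    def test_weighted_fit_accepts_pseudo_likelihood_weights(self):
        rng = np.random.default_rng(8)
        df = _sim_frame(rng, n=800, group_effects=[0.4, -0.4, 0.2, -0.2])
        fit = fit_random_intercept_logistic(df, "y", "x", weight_col="weight")
        assert fit.converged
        assert fit.sigma_u > 0


class TestMarginalEffects:
    def test_zero_coefficient_gives_zero_effect(self):
        rng = np.random.default_rng(4)
        fit = fit_weighted_logistic(_sim_frame(rng), "y", "x")
        fit.params["x"] = 0.0
        (me,) = average_marginal_effect(fit, "x")
        assert me.effect_pp == 0.0

    def test_continuous_effect_matches_closed_form(self):
        """One-covariate logistic: the +1-SD effect equals the averaged
        logistic differences computed directly from the coefficients."""
        rng = np.random.default_rng(5)
        df = _sim_frame(rng, n=600).assign(weight=1.0)
        fit = fit_weighted_logistic(df, "y", "x")
        (me,) = average_marginal_effect(fit, "x")
        a, b = fit.params["Intercept"], fit.params["x"]
        x = fit.frame["x"].to_numpy()
        sd = x.std()  # weighted SD with unit weights
        want = np.mean(expit(a + b * (x + sd)) - expit(a + b * x)) * 100
        assert me.effect_pp == pytest.approx(want, abs=1e-10)
        assert me.scaling == "per_sd_above_mean"

    def test_binary_exposure_equals_weighted_risk_difference(self):
        """Saturated 2x2 model: the discrete effect is the weighted risk
        difference in percentage points."""
        rng = np.random.default_rng(6)
        n = 2000
        g = rng.random(n) < 0.4
        y = (rng.random(n) < np.where(g, 0.55, 0.35)).astype(int)
        df = pd.DataFrame(
            {
                "y": y,
                "g": np.where(g, "present", "absent"),
                "weight": rng.lognormal(0, 0.4, n),
                "cluster_id": rng.integers(0, 50, n),
            }
        )
        fit = fit_weighted_logistic(df, "y", "g")
        (me,) = average_marginal_effect(fit, "g")
        w = df["weight"]
        rd = (
            np.average(y[g], weights=w[g]) - np.average(y[~g], weights=w[~g])
        ) * 100
        assert me.effect_pp == pytest.approx(rd, abs=1e-6)
        assert me.level == "present"
        assert me.scaling == "discrete_from_reference"

    def test_effect_sign_matches_coefficient_sign(self):
        rng = np.random.default_rng(7)
        for beta in (-0.8, -0.2, 0.3, 0.9):
            df = _sim_frame(rng, n=800, beta=beta)
            fit = fit_weighted_logistic(df, "y", "x")
            (me,) = average_marginal_effect(fit, "x")
            assert np.sign(me.effect_pp) == np.sign(fit.params["x"])

    def test_absent_variable_rejected(self):
        rng = np.random.default_rng(9)
        fit = fit_weighted_logistic(_sim_frame(rng), "y", "x")
        with pytest.raises(KeyError, match="nope"):
            average_marginal_effect(fit, "nope")


def test_stars():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.009) == "**"
    assert significance_stars(0.0009) == "***"


@pytest.fixture(scope="module")
def toy_table():
    rng = np.random.default_rng(12)
    n = 1200
    rounds = np.array(["2000", "2005", "2011", "2016"])[rng.integers(0, 4, n)]
    constraint = rng.random(n)
    degree = rng.integers(1, 9, n).astype(float)
    eta = -0.2 + 0.6 * (constraint - 0.5)
    mmf = (rng.random(n) < expit(eta)).astype(object)
    mdd = (rng.random(n) < expit(eta - 1.5)).astype(object)
    mdd[rounds == "2000"] = None
    mmf[rounds == "2005"] = None
    return pd.DataFrame(
        {
            "round": rounds,
            "mdd_met": mdd,
            "mmf_met": mmf,
            "constraint": constraint,
            "degree": degree,
            "weight": rng.lognormal(0, 0.3, n),
            "cluster_id": rng.integers(0, 40, n),
            "resp_age_years": rng.normal(28, 6, n),
        }
    )


@pytest.fixture(scope="module")
def results(toy_table):
    return run_association_suite(
        toy_table,
        exposures=("constraint", "degree"),
        covariates=("resp_age_years",),
    )


class TestAssociationSuite:
    def test_output_schema(self, results):
        assoc = results.associations
        assert set(assoc.columns) >= {
            "outcome", "exposure", "round", "model", "odds_ratio",
            "ci_low", "ci_high", "p_value", "stars", "n", "available",
        }
        assert set(assoc["model"]) == {"crude", "adjusted"}
        assert "pooled" in set(assoc["round"])
        ames = results.marginal_effects
        assert set(ames.columns) >= {"outcome", "exposure", "effect_pp", "ci_low", "ci_high"}

    def test_masked_round_cells_marked_unavailable(self, results):
        assoc = results.associations
        mdd_2000 = assoc[(assoc.outcome == "mdd_met") & (assoc["round"] == "2000")]
        assert (~mdd_2000["available"]).all()
        mmf_2005 = assoc[(assoc.outcome == "mmf_met") & (assoc["round"] == "2005")]
        assert (~mmf_2005["available"]).all()
        # every other round is fitted
        mmf_2011 = assoc[(assoc.outcome == "mmf_met") & (assoc["round"] == "2011")]
        assert mmf_2011["available"].all()

    def test_pooled_effect_direction_recovered(self, results):
        pooled = results.associations.query(
            "outcome == 'mmf_met' and exposure == 'constraint' and round == 'pooled'"
        )
        assert (pooled["odds_ratio"] > 1).all()  # positive simulated effect
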