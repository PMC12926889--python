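"""Mixed-model estimation, Rubin pooling, baseline balance."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from trialcea._lmm import fit_nested_lmm
from trialcea.estimation import (
    ArmEstimate,
    ModelSpec,
    baseline_balance,
    build_design,
    fit_cost_model,
    fit_effect_model,
    fit_zi_cost_model,
    pool_fit_results,
    rubin_pool,
)
from trialcea.simulate import (
    simulate_clustered_gamma,
    simulate_clustered_gaussian,
    simulate_two_part,
)


class TestNestedLMM:
    def test_matches_statsmodels_mixedlm(self):
        """Independent oracle: statsmodels MixedLM with practice-in-centre
        variance components on the same data."""
        rng = np.random.default_rng(3)
        d = simulate_clustered_gaussian(600, {"gp": 0.05}, rng,
                                        sd_centre=0.08, sd_practice=0.10)
        X, names, _ = build_design(d, ("z0", "z1"))
        mine = fit_nested_lmm(d["y"], X, d["centre_id"], d["practice_id"],
                              names=names)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = MixedLM.from_formula(
                "y ~ C(arm, Treatment('none')) + z0 + z1", d,
                groups="centre_id", re_formula="1",
                vc_formula={"practice": "0 + C(practice_id)"},
            ).fit(reml=True)
        np.testing.assert_allclose(mine.beta, ref.params[:-2], rtol=2e-3,
                                   atol=1e-5)
        np.testing.assert_allclose(mine.se, ref.bse[:-2], rtol=5e-3,
                                   atol=1e-5)
        assert mine.var_centre == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), abs=2e-3
        )
        assert mine.var_practice == pytest.approx(
            float(ref.vcomp[0]), abs=2e-3
        )

    def test_zero_cluster_variance_reduces_to_ols(self):
        """With no cluster variability the REML optimum sits on the
        boundary and the fit is exactly ordinary least squares.  Sampling
        noise can push a draw's apparent ICC slightly positive, so the
        exact-equality check applies to the boundary fits and a looser
        one to the rest."""
        rng = np.random.default_rng(4)
        n_boundary = 0
        for _ in range(6):
            d = simulate_clustered_gaussian(400, {}, rng, sd_centre=0.0,
                                            sd_practice=0.0)
            X, names, _ = build_design(d, ("z0", "z1"))
            mine = fit_nested_lmm(d["y"], X, d["centre_id"], d["practice_id"])
            ols = sm.OLS(d["y"].to_numpy(), X).fit()
            if mine.var_centre == 0.0 and mine.var_practice == 0.0:
                n_boundary += 1
                np.testing.assert_allclose(mine.beta, ols.params, atol=1e-6)
                np.testing.assert_allclose(mine.se, ols.bse, atol=1e-6)
                assert mine.singular
            else:
                np.testing.assert_allclose(mine.beta, ols.params, atol=5e-3)
        assert n_boundary >= 1


class TestEffectModel:
    def test_recovers_configured_effect(self):
        rng = np.random.default_rng(5)
        d = simulate_clustered_gaussian(900, {"gp": 0.05}, rng)
        fit = fit_effect_model(d, ModelSpec("y", covariates=("z0", "z1")))
        e = fit.arm_estimates["gp"]
        assert e.estimate == pytest.approx(0.05, abs=4 * e.se)
        assert fit.method == "nested-lmm-reml"
        assert 0 < e.p <= 1

    def test_reference_arm_contract(self):
        """Contrasts are intervention − no-feedback: raising the reference
        arm's outcome flips the sign of both contrasts."""
        rng = np.random.default_rng(6)
        d = simulate_clustered_gaussian(900, {}, rng)
        d.loc[d["arm"] == "none", "y"] += 1.0
        fit = fit_effect_model(d, ModelSpec("y", covariates=("z0", "z1")))
        assert fit.arm_estimates["gp"].estimate < 0
        assert fit.arm_estimates["gp_plus_patient"].estimate < 0


class TestCostModel:
    def test_unclustered_reduces_to_gamma_glm(self):
        """Single-cluster data: the PQL fit collapses to the plain gamma
        GLM oracle."""
        rng = np.random.default_rng(7)
        n = 500
        d = pd.DataFrame({
            "arm": rng.choice(["none", "gp", "gp_plus_patient"], n),
            "centre_id": "C1", "practice_id": "P1",
        })
        mu = np.exp(6.0 + 0.2 * (d["arm"] == "gp"))
        d["y"] = rng.gamma(2.0, mu / 2.0)
        fit = fit_cost_model(d, ModelSpec("y", family="gamma-log",
                                          covariates=()))
        X, _, _ = build_design(d, ())
        ref = sm.GLM(d["y"], X,
                     family=sm.families.Gamma(sm.families.links.Log())).fit()
        assert fit.arm_estimates["gp"].estimate == pytest.approx(
            float(ref.params[1]), abs=1e-4
        )
        assert fit.arm_estimates["gp"].se == pytest.approx(
            float(ref.bse[1]), abs=1e-4
        )

    def test_identical_outcomes_give_null_ratio(self):
        rng = np.random.default_rng(8)
        d = simulate_clustered_gamma(300, {}, rng)
        d["y"] = 500.0
        fit = fit_cost_model(d, ModelSpec("y", family="gamma-log",
                                          covariates=()))
        assert fit.arm_estimates["gp"].estimate == pytest.approx(0.0, abs=1e-8)
        assert fit.ratio("gp") == pytest.approx(1.0, abs=1e-8)

    def test_zero_outcomes_replaced_not_dropped(self):
        rng = np.random.default_rng(9)
        d = simulate_clustered_gamma(300, {}, rng)
        d.loc[:4, "y"] = 0.0
        fit = fit_cost_model(d, ModelSpec("y", family="gamma-log",
                                          covariates=("z0", "z1")))
        assert fit.n_obs == 300
        assert any("zero-cost" in w for w in fit.warnings)

    def test_recovers_cost_ratio(self):
        rng = np.random.default_rng(10)
        d = simulate_clustered_gamma(900, {"gp": 1.2}, rng)
        fit = fit_cost_model(d, ModelSpec("y", family="gamma-log",
                                          covariates=("z0", "z1")))
        e = fit.arm_estimates["gp"]
        assert e.estimate == pytest.approx(np.log(1.2), abs=4 * e.se)


class TestTwoPartModel:
    def test_no_zeros_collapses_to_gamma_fit(self):
        rng = np.random.default_rng(11)
        d = simulate_two_part(600, {"gp": 1.3}, rng, zero_prob=0.0)
        spec_zi = ModelSpec("y", family="zi-gamma-log", covariates=("z0", "z1"))
        spec_g = ModelSpec("y", family="gamma-log", covariates=("z0", "z1"))
        zi = fit_zi_cost_model(d, spec_zi)
        g = fit_cost_model(d, spec_g)
        assert zi.arm_estimates["gp"].estimate == pytest.approx(
            g.arm_estimates["gp"].estimate, abs=1e-6
        )
        assert zi.method.startswith("two-part/")

    def test_marginal_mean_formula_against_monte_carlo(self):
        """(1 − π)·µ equals the empirical mean of a large two-part draw."""
        rng = np.random.default_rng(12)
        pi, mu, shape = 0.4, 500.0, 2.0
        draws = rng.gamma(shape, mu / shape, size=1_000_000)
        draws[rng.random(1_000_000) < pi] = 0.0
        expected = (1 - pi) * mu
        se = draws.std() / 1000.0
        assert draws.mean() == pytest.approx(expected, abs=4 * se)

    def test_recovers_marginal_ratio(self):
        rng = np.random.default_rng(13)
        d = simulate_two_part(900, {"gp": 1.3}, rng)
        fit = fit_zi_cost_model(
            d, ModelSpec("y", family="zi-gamma-log", covariates=("z0", "z1"))
        )
        e = fit.arm_estimates["gp"]
        assert e.estimate == pytest.approx(np.log(1.3), abs=4 * e.se)

    def test_all_zero_arm_flagged(self):
        rng = np.random.default_rng(14)
        d = simulate_two_part(300, {}, rng, zero_prob=0.3)
        d.loc[d["arm"] == "gp", "y"] = 0.0
        fit = fit_zi_cost_model(
            d, ModelSpec("y", family="zi-gamma-log", covariates=())
        )
        assert any("separation" in w for w in fit.warnings)


class TestRubinPooling:
    def test_identical_fits_have_no_between_variance(self):
        ests = [ArmEstimate(2.0, 0.5, 900.0, 0.01)] * 5
        pe = rubin_pool(ests)
        assert pe.estimate == 2.0
        assert pe.between == 0.0
        assert pe.se == pytest.approx(0.5)
        assert pe.df == 900.0

    def test_hand_worked_two_imputation_example(self):
        pe = rubin_pool([1.0, 3.0], [1.0, 1.0], df_com=1000)
        assert pe.estimate == 2.0
        assert pe.within == 1.0
        assert pe.between == 2.0
        assert pe.total == pytest.approx(1.0 + 1.5 * 2.0)
        assert pe.se == pytest.approx(2.0)
        assert pe.ci_low < pe.estimate < pe.ci_high

    def test_interval_widens_with_between_variance(self):
        widths = []
        for spread in (0.0, 0.5, 1.0, 2.0):
            pe = rubin_pool([2.0 - spread, 2.0 + spread], [1.0, 1.0],
                            df_com=500)
            widths.append(pe.ci_high - pe.ci_low)
        assert widths == sorted(widths)

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="M >= 2"):
            rubin_pool([1.0], [1.0], df_com=10)

    def test_pooled_mean_is_average_of_estimates(self):
        rng = np.random.default_rng(15)
        ests = rng.normal(0, 1, 20)
        pe = rubin_pool(ests, np.full(20, 0.5), df_com=100)
        assert pe.estimate == pytest.approx(ests.mean())

    def test_heterogeneous_specs_rejected(self):
        rng = np.random.default_rng(16)
        d = simulate_clustered_gaussian(300, {}, rng)
        f1 = fit_effect_model(d, ModelSpec("y", covariates=("z0",)))
        f2 = fit_effect_model(d, ModelSpec("y", covariates=("z0", "z1")))
        with pytest.raises(ValueError, match="heterogeneous"):
            pool_fit_results([f1, f2], "gp")


class TestBaselineBalance:
    def test_constant_binary_flagged_not_fitted(self, small_trial):
        df = small_trial.df.copy()
        df["insurance_plan"] = 1.0
        tab = baseline_balance(df).set_index("variable")
        assert "constant" in tab.loc["insurance_plan", "note"]
        assert np.isnan(tab.loc["insurance_plan", "p_gp"])

    def test_identical_distribution_gives_large_p(self, small_trial):
        df = small_trial.df.copy()
        df["age"] = 40.0 + np.tile([0, 1, 2], len(df) // 3 + 1)[: len(df)]
        rng = np.random.default_rng(0)
        df["age"] = rng.permutation(df["age"].to_numpy())
        tab = baseline_balance(df, {"age": "continuous"}).set_index("variable")
        assert tab.loc["age", "p_gp"] > 0.01

    def test_injected_shift_detected(self, default_trial):
        df = default_trial.df.copy()
        sd = df["age"].std()
        df.loc[df["arm"] == "gp", "age"] += sd  # 1-s.d. shift at n=987
        tab = baseline_balance(df, {"age": "continuous"}).set_index("variable")
        assert tab.loc["age", "p_gp"] < 0.001
        assert tab.loc["age", "p_gp_plus_patient"] > 0.001

    def test_full_table_shape(self, default_trial):
        tab = baseline_balance(default_trial.df)
        assert {"variable", "test", "p_gp", "p_gp_plus_patient"} <= set(
            tab.columns
        )
        assert set(tab["test"]) == {"continuous", "binary", "categorical"}
        ps = tab[["p_gp", "p_gp_plus_patient"]].to_numpy()
        ps = ps[~np.isnan(ps)]
        assert ((ps >= 0) & (ps <= 1)).all()
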