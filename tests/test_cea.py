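"""Decision analytics: ICERs, net benefit, CEACs, scenarios, subgroups."""

import numpy as np
import pandas as pd
import pytest

from trialcea.cea import (
    SubgroupDef,
    WTPGrid,
    ce_probability,
    ceac,
    icer,
    make_scenario,
    net_benefit,
    prepare_outcomes,
    run_scenario,
    run_subgroup,
)
from trialcea.estimation import ModelSpec, SUBGROUP_COVARIATES, fit_effect_model
from trialcea.imputation import ImputationStack, mice_impute
from trialcea.simulate import simulate_clustered_gaussian
from trialcea.synthetic_trial import (
    ArmEffect,
    StratumEffect,
    TrialConfig,
    generate_trial,
)


class TestICER:
    def test_north_east_trade_off(self):
        res = icer(100.0, 0.01)
        assert res.icer == pytest.approx(10_000.0)
        assert res.classification == "trade-off NE"

    def test_dominant_quadrant(self):
        assert icer(-50.0, 0.02).classification == "intervention dominant"

    def test_zero_effect_is_cost_minimisation(self):
        res = icer(25.0, 0.0)
        assert np.isnan(res.icer)
        assert not res.defined
        assert res.classification == "cost-minimisation"

    @pytest.mark.parametrize(
        "dc, de",
        [(100.0, 0.01), (-50.0, 0.02), (30.0, -0.01), (-10.0, -0.05)],
    )
    def test_negation_swaps_dominance_keeps_ratio(self, dc, de):
        a, b = icer(dc, de), icer(-dc, -de)
        assert a.icer == pytest.approx(b.icer)
        swap = {
            "intervention dominant": "intervention dominated",
            "intervention dominated": "intervention dominant",
            "trade-off NE": "trade-off SW",
            "trade-off SW": "trade-off NE",
        }
        assert b.classification == swap[a.classification]


class TestNetBenefit:
    def test_zero_wtp_is_negative_cost(self):
        assert net_benefit(1000.0, 0.5, 0.0) == -1000.0

    def test_worked_example(self):
        assert net_benefit(1000.0, 0.5, 10_000.0) == 4000.0

    def test_linearity_in_lambda(self):
        nb1 = net_benefit(100.0, 0.3, 1000.0)
        nb2 = net_benefit(100.0, 0.3, 2000.0)
        nb3 = net_benefit(100.0, 0.3, 3000.0)
        assert nb3 - nb2 == pytest.approx(nb2 - nb1)

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValueError):
            net_benefit(1.0, 1.0, -1.0)


class TestCEProbability:
    def test_half_p_rule(self):
        assert ce_probability(2.0, 0.10) == pytest.approx(0.95)
        assert ce_probability(-2.0, 0.10) == pytest.approx(0.05)
        assert ce_probability(0.0, 1.0) == 0.5

    def test_probabilities_stay_inside_unit_interval(self):
        for p in (1e-12, 0.5, 1.0):
            for c in (-1.0, 1.0):
                assert 0.0 < ce_probability(c, p) < 1.0

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValueError):
            ce_probability(1.0, bad)


class TestWTPGrid:
    def test_default_qaly_grid(self):
        g = WTPGrid.qaly_default()
        assert len(g.values) == 17
        assert g.values[0] == 0.0 and g.values[-1] == 160_000.0
        assert np.all(np.diff(g.values) == 10_000.0)

    def test_default_dfd_grid(self):
        g = WTPGrid.dfd_default()
        assert len(g.values) == 11
        assert g.values[-1] == 200.0 and np.all(np.diff(g.values) == 20.0)

    def test_empty_or_unsorted_rejected(self):
        with pytest.raises(ValueError):
            WTPGrid(())
        with pytest.raises(ValueError):
            WTPGrid((1.0, 1.0))


@pytest.fixture(scope="module")
def outcome_frames(tables, small_trial):
    table, _, cpi = tables
    return [prepare_outcomes(small_trial.df, table, cpi)]


class TestCEAC:
    def test_zero_wtp_equals_negated_cost_regression(self, outcome_frames):
        covs = ("age", "phq9_T0")
        curves = ceac(outcome_frames, WTPGrid((0.0, 10_000.0)), covariates=covs)
        cost_fit = fit_effect_model(
            outcome_frames[0], ModelSpec("cost", covariates=covs)
        )
        for comp, curve in curves.items():
            at_zero = curve.loc[curve["lambda"] == 0.0].iloc[0]
            assert at_zero["estimate"] == pytest.approx(
                -cost_fit.arm_estimates[comp].estimate, abs=1e-6
            )

    def test_large_wtp_converges_to_effect_model(self, outcome_frames):
        covs = ("age", "phq9_T0")
        lam = 1e9
        curves = ceac(outcome_frames, WTPGrid((lam,)), covariates=covs)
        eff_fit = fit_effect_model(
            outcome_frames[0], ModelSpec("effect", covariates=covs)
        )
        for comp, curve in curves.items():
            scaled = curve["estimate"].iloc[0] / lam
            assert scaled == pytest.approx(
                eff_fit.arm_estimates[comp].estimate, rel=1e-3
            )

    def test_probabilities_within_open_unit_interval(self, outcome_frames):
        curves = ceac(outcome_frames, WTPGrid.qaly_default(),
                      covariates=("age",))
        for curve in curves.values():
            assert ((curve["probability"] > 0) & (curve["probability"] < 1)).all()

    def test_null_simulation_mean_probability_near_half(self):
        """Under a configured null the expected CEAC height is 0.5 at
        every λ; the Monte-Carlo mean over replicates must sit in a
        generous band around it."""
        rng = np.random.default_rng(30)
        lams = (0.0, 80_000.0, 160_000.0)
        probs = {lam: [] for lam in lams}
        for _ in range(40):
            d = simulate_clustered_gaussian(240, {}, rng)
            d = d.rename(columns={"y": "effect"})
            d["cost"] = np.exp(rng.normal(7.0, 0.8, len(d)))
            curves = ceac([d], WTPGrid(lams), covariates=("z0", "z1"))
            for comp in curves:
                for lam in lams:
                    row = curves[comp].loc[curves[comp]["lambda"] == lam]
                    probs[lam].append(float(row["probability"].iloc[0]))
        for lam in lams:
            assert 0.3 < np.mean(probs[lam]) < 0.7


class TestScenarios:
    def test_payer_scenario_contracts(self):
        sc = make_scenario("payer")
        assert sc.perspective == "payer"
        assert "sick_days_T0" not in sc.covariates

    def test_payer_with_sick_day_covariate_rejected(self):
        from trialcea.cea import ScenarioConfig
        with pytest.raises(ValueError, match="sick days"):
            ScenarioConfig("bad", perspective="payer")

    def test_complete_case_on_complete_data_matches_base(self, tables,
                                                         small_trial):
        table, _, cpi = tables
        stack = mice_impute(small_trial, m=2, iterations=1)
        base = run_scenario(stack, make_scenario("base_societal"), table, cpi)
        cc = run_scenario(stack, make_scenario("complete_case"), table, cpi)
        assert cc.n_analysed == base.n_analysed == small_trial.n
        merged = base.estimates.merge(
            cc.estimates, on=["outcome", "comparison"], suffixes=("_b", "_c")
        )
        np.testing.assert_allclose(
            merged["estimate_b"], merged["estimate_c"], atol=1e-8
        )

    def test_dfd_scenario_reports_days_on_dfd_grid(self, tables, small_trial):
        table, _, cpi = tables
        stack = mice_impute(small_trial, m=1, iterations=1)
        res = run_scenario(stack, make_scenario("dfd"), table, cpi)
        assert res.scenario.effect == "dfd"
        for curve in res.ceacs.values():
            assert curve["lambda"].max() == 200.0
        eff = res.estimates.query("outcome == 'dfd'")
        # effects are on the day scale: SE of an arm difference in days
        assert (eff["se"] > 1.0).all()

    def test_payer_totals_bounded_by_societal(self, tables, small_trial):
        table, _, cpi = tables
        soc = prepare_outcomes(small_trial.df, table, cpi,
                               perspective="societal")
        pay = prepare_outcomes(small_trial.df, table, cpi,
                               perspective="payer")
        assert (soc["cost"] >= pay["cost"] - 1e-9).all()


class TestSubgroups:
    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="subgroup variable"):
            SubgroupDef("shoe_size")

    def test_reduced_covariate_contract(self, tables, small_trial):
        table, _, cpi = tables
        stack = mice_impute(small_trial, m=1, iterations=1)
        results = run_subgroup(stack, SubgroupDef("depression_history"),
                               make_scenario("base_societal"), table, cpi)
        for res in results.values():
            covs = res.scenario.covariates
            assert "pregnancy" not in covs
            assert "breastfeeding" not in covs
            assert "living_situation" not in covs
            assert "city_size" not in covs and "city_size_binary" in covs
            assert "depression_history" not in covs

    def test_constant_split_reproduces_unsplit_analysis(self, tables,
                                                        small_trial):
        table, _, cpi = tables
        data = small_trial.copy()
        data.df["addiction"] = 0.0
        stack = mice_impute(data, m=1, iterations=1)
        sub = run_subgroup(stack, SubgroupDef("addiction"),
                           make_scenario("base_societal"), table, cpi)
        assert list(sub) == [0.0]
        covs = tuple(c for c in SUBGROUP_COVARIATES if c != "addiction")
        from dataclasses import replace
        direct = run_scenario(
            stack, replace(make_scenario("base_societal"), covariates=covs),
            table, cpi,
        )
        np.testing.assert_allclose(
            sub[0.0].estimates["estimate"], direct.estimates["estimate"],
            atol=1e-8,
        )

    def test_stratum_specific_effect_raises_stratum_ceac(self, tables):
        """Heterogeneity driver: a dominant effect confined to the
        MINI-confirmed stratum shows up as a markedly higher CEAC there
        than in its complement."""
        table, _, cpi = tables
        config = TrialConfig(
            n_per_arm=250, n_practices=16, n_centres=4, seed=17,
            heterogeneity=StratumEffect(
                variable="mini_depression_T1", level=1.0,
                arm_effects={
                    "gp_plus_patient": ArmEffect(utility_shift=0.12,
                                                 cost_ratio=0.5),
                },
            ),
        )
        data = generate_trial(config)
        stack = mice_impute(data, m=1, iterations=1)
        results = run_subgroup(stack, SubgroupDef("mini_depression_T1"),
                               make_scenario("base_societal"), table, cpi)
        hi = results[1.0].ceacs["gp_plus_patient"]["probability"].mean()
        lo = results[0.0].ceacs["gp_plus_patient"]["probability"].mean()
        assert hi > lo + 0.2
        assert hi > 0.8
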