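"""Synthetic trial generator: design, distributions, missingness."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import trialcea.schema as schema
from trialcea.instruments import qaly_auc
from trialcea.synthetic_trial import (
    ArmEffect,
    CostParams,
    DEFAULT_COST_PARAMS,
    TrialConfig,
    apply_missingness,
    expected_qaly_difference,
    generate_trial,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_per_arm": 0}, "n_per_arm"),
            ({"missing_rate_target": 1.0}, "missing_rate_target"),
            ({"missing_rate_target": -0.1}, "missing_rate_target"),
            ({"n_practices": 2, "n_centres": 5}, "n_practices"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, field):
        with pytest.raises(ValueError, match=field):
            TrialConfig(**kwargs)

    def test_arm_effects_must_cover_three_arms(self):
        with pytest.raises(ValueError, match="arm_effects"):
            TrialConfig(arm_effects={"none": ArmEffect(), "gp": ArmEffect()})

    def test_cost_zero_probability_bounds(self):
        params = dict(DEFAULT_COST_PARAMS)
        params["gp_visit"] = CostParams(1.5, 1.0, 1.0)
        with pytest.raises(ValueError, match="zero_prob"):
            TrialConfig(cost_params=params)


class TestGeneration:
    def test_three_equal_arms_at_published_size(self, default_trial):
        df = default_trial.df
        assert len(df) == 987
        assert df["arm"].value_counts().to_dict() == {
            "none": 329, "gp": 329, "gp_plus_patient": 329,
        }

    def test_same_seed_reproduces_identical_dataset(self, small_config,
                                                    small_trial):
        again = generate_trial(small_config)
        pd.testing.assert_frame_equal(small_trial.df, again.df)

    def test_inclusion_criterion_floor(self, default_trial):
        assert (default_trial.df["phq9_T0"] >= 10).all()

    def test_cluster_nesting_and_coverage(self, default_trial):
        df = default_trial.df
        mapping = df.groupby("practice_id")["centre_id"].nunique()
        assert (mapping == 1).all()
        assert set(df["arm"]) == set(schema.ARMS)

    def test_baseline_moments_match_target_population(self, default_trial):
        df = default_trial.df
        assert df["phq9_T0"].mean() == pytest.approx(13.5, abs=0.5)
        assert df["phq9_T0"].std() == pytest.approx(3.3, abs=0.6)
        assert df["eq5d_index_T0"].mean() == pytest.approx(0.675, abs=0.05)
        assert df["eq5d_index_T0"].std() == pytest.approx(0.261, abs=0.06)
        assert (df["gender"] == "female").mean() == pytest.approx(0.622, abs=0.05)
        assert df["age"].mean() == pytest.approx(39.5, abs=1.5)

    def test_health_improves_in_every_arm(self, default_trial):
        df = default_trial.df
        for arm in schema.ARMS:
            sub = df[df["arm"] == arm]
            means = [sub[f"eq5d_index_{t}"].mean() for t in schema.TIMEPOINTS]
            assert means[0] < means[-1]
            phq = [sub[f"phq9_{t}"].mean() for t in schema.TIMEPOINTS]
            assert phq[0] > phq[-1]

    def test_phq_items_sum_to_totals(self, small_trial):
        df = small_trial.df
        for t in schema.TIMEPOINTS:
            items = df[schema.phq9_item_columns(t)].to_numpy()
            assert np.all((items >= 0) & (items <= 3))
            assert np.array_equal(items.sum(axis=1), df[f"phq9_{t}"].to_numpy())

    def test_two_part_zero_fractions_converge(self):
        config = TrialConfig(n_per_arm=3334, seed=2)  # ~10k participants
        df = generate_trial(config).df
        for cat in ("gp_visit", "inpatient_day", "psychotherapy_session"):
            p = config.cost_params[cat].zero_prob
            frac = (df[f"{cat}_T2"] == 0).mean()
            tol = 4 * np.sqrt(p * (1 - p) / len(df))
            assert abs(frac - p) < tol

    def test_null_config_gives_null_qaly_contrast(self):
        config = TrialConfig(n_per_arm=2000, seed=4)
        assert expected_qaly_difference(config, "gp") == 0.0
        df = generate_trial(config).df
        q = qaly_auc(df[[f"eq5d_index_{t}" for t in schema.TIMEPOINTS]].to_numpy())
        df = df.assign(q=q)
        means = df.groupby("arm")["q"].agg(["mean", "std", "count"])
        for arm in ("gp", "gp_plus_patient"):
            diff = means.loc[arm, "mean"] - means.loc["none", "mean"]
            se = np.sqrt(
                means.loc[arm, "std"] ** 2 / means.loc[arm, "count"]
                + means.loc["none", "std"] ** 2 / means.loc["none", "count"]
            )
            assert abs(diff) < 3.5 * se

    def test_configured_utility_shift_moves_qalys(self):
        config = TrialConfig(
            n_per_arm=2000, seed=4,
            arm_effects={
                "none": ArmEffect(), "gp": ArmEffect(utility_shift=0.1),
                "gp_plus_patient": ArmEffect(),
            },
        )
        df = generate_trial(config).df
        q = qaly_auc(df[[f"eq5d_index_{t}" for t in schema.TIMEPOINTS]].to_numpy())
        df = df.assign(q=q)
        diff = df.groupby("arm")["q"].mean()["gp"] - df.groupby("arm")["q"].mean()["none"]
        expected = expected_qaly_difference(config, "gp")
        # discretisation to 5-digit states attenuates the latent shift
        assert 0.5 * expected < diff < 1.2 * expected


class TestMissingness:
    def test_zero_target_is_identity(self, small_trial):
        config = TrialConfig(n_per_arm=60, n_centres=3, n_practices=12,
                             seed=11, missing_rate_target=0.0)
        out = apply_missingness(small_trial, config)
        pd.testing.assert_frame_equal(out.df, small_trial.df)

    def test_realized_rate_hits_target(self):
        config = TrialConfig(seed=8)
        out = apply_missingness(generate_trial(config))
        realized = out.missingness_info["realized_cell_fraction"]
        assert abs(realized - 0.20) < 0.03

    def test_design_and_baseline_never_missing(self, small_trial_missing):
        df = small_trial_missing.df
        protected = (
            list(schema.DESIGN_COLUMNS) + list(schema.BASELINE_COVARIATES)
            + list(schema.BASELINE_USE)
            + ["eq5d_T0", "phq9_T0"]
        )
        assert not df[protected].isna().any().any()

    def test_mar_mechanism_signs_recovered_at_scale(self):
        """Logistic regression of the missingness indicator on baseline
        predictors recovers the configured coefficient signs."""
        config = TrialConfig(n_per_arm=6700, seed=13)
        out = apply_missingness(generate_trial(config))
        df = out.df
        miss = df["eq5d_T2"].isna().astype(float)
        X = sm.add_constant(np.column_stack([
            1.0 - df["native_speaker"], df["smoker"], df["addiction"],
            df["eq5d_index_T0"], df["phq9_T0"], df["gp_visits_T0"],
        ]))
        fit = sm.Logit(miss, X).fit(disp=0)
        signs = np.sign(fit.params[1:])
        assert list(signs) == [1, 1, 1, -1, 1, 1]
        assert (fit.pvalues[1:] < 0.01).all()

    def test_unreachable_target_warns(self, small_trial):
        config = TrialConfig(n_per_arm=60, n_centres=3, n_practices=12,
                             seed=11, missing_rate_target=1 - 1e-12)
        with pytest.warns(UserWarning, match="unreachable"):
            apply_missingness(small_trial, config)


class TestFixtures:
    def test_unit_costs_nonnegative_with_price_years(self, tables):
        table, _, _ = tables
        tab = table.table
        assert (tab["unit_cost"] >= 0).all()
        assert tab["price_year"].between(2015, 2023).all()

    def test_cpi_covers_all_price_years(self, tables):
        table, _, cpi = tables
        for year in table.table["price_year"].unique():
            assert int(year) in cpi
        assert 2022 in cpi
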