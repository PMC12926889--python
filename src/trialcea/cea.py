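"""Decision analytics: ICERs, net-benefit regression, CEACs, scenarios.

The cost-effectiveness probability at willingness-to-pay λ comes from a
net-benefit regression (NBR): each participant's net monetary benefit
λ·effect − cost is regressed on the arm indicators and the adjustment
covariates with the same nested random-effects structure as the effect
models, fitted per imputed dataset, Rubin-pooled, and converted with
the half-p rule — 1 − p/2 when the pooled arm coefficient is positive,
p/2 when negative (0.5 at exactly zero).  All comparisons are pairwise
against the no-feedback arm; no three-arm contrast is ever produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from . import schema
from .costing import CPISeries, UnitCostTable, compute_cost_bundle
from .estimation import (
    BASE_COVARIATES,
    SUBGROUP_COVARIATES,
    ModelSpec,
    fit_cost_model,
    fit_effect_model,
    fit_zi_cost_model,
    pool_fit_results,
    rubin_pool,
)
from .imputation import ImputationStack
from .instruments import dfd_auc, qaly_auc
from .synthetic_trial import TrialDataset
from .schema import ARMS, FOLLOWUP

__all__ = [
    "WTPGrid",
    "ICERResult",
    "ScenarioConfig",
    "SubgroupDef",
    "ScenarioResult",
    "icer",
    "net_benefit",
    "ce_probability",
    "ceac",
    "run_scenario",
    "run_subgroup",
    "make_scenario",
    "plot_ceac",
]

COMPARISONS = tuple(ARMS[1:])  # each intervention vs no feedback


@dataclass(frozen=True)
class WTPGrid:
    """Willingness-to-pay grid (strictly increasing λ values)."""

    values: tuple[float, ...]
    effect_unit: str = "QALY"

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("WTP grid is empty")
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("WTP grid must be strictly increasing")

    @classmethod
    def qaly_default(cls) -> "WTPGrid":
        return cls(tuple(float(v) for v in range(0, 160_001, 10_000)), "QALY")

    @classmethod
    def dfd_default(cls) -> "WTPGrid":
        return cls(tuple(float(v) for v in range(0, 201, 20)), "DFD")


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_effect: float
    icer: float          # nan when undefined (ΔE = 0)
    classification: str  # dominant | dominated | trade-off NE | trade-off SW
                         # | cost-minimisation

    @property
    def defined(self) -> bool:
        return not np.isnan(self.icer)


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost-effectiveness ratio with dominance classification.

    ΔE = 0 yields an undefined ratio tagged cost-minimisation rather
    than an exception.
    """
    dc, de = float(delta_cost), float(delta_effect)
    if de == 0.0:
        return ICERResult(dc, de, float("nan"), "cost-minimisation")
    ratio = dc / de
    if dc <= 0 and de > 0:
        cls = "intervention dominant"
    elif dc >= 0 and de < 0:
        cls = "intervention dominated"
    elif dc > 0 and de > 0:
        cls = "trade-off NE"
    else:
        cls = "trade-off SW"
    return ICERResult(dc, de, ratio, cls)


def net_benefit(cost, effect, lam: float):
    """Net monetary benefit λ·effect − cost (per participant)."""
    if lam < 0:
        raise ValueError("willingness to pay must be non-negative")
    return lam * np.asarray(effect, dtype=float) - np.asarray(cost, dtype=float)


def ce_probability(coefficient: float, p_value: float) -> float:
    """Half-p rule: 1 − p/2 for a positive net-benefit coefficient,
    p/2 for a negative one, 0.5 at exactly zero."""
    if not 0.0 < p_value <= 1.0:
        raise ValueError("p-value must be in (0, 1]")
    if coefficient > 0:
        return 1.0 - p_value / 2.0
    if coefficient < 0:
        return p_value / 2.0
    return 0.5


# --------------------------------------------------------------------------
# scenarios

@dataclass(frozen=True)
class ScenarioConfig:
    """One analysis scenario (base case or sensitivity analysis)."""

    name: str
    perspective: str = "societal"          # societal | payer
    effect: str = "qaly"                   # qaly | dfd
    covariates: tuple[str, ...] = BASE_COVARIATES
    grid: WTPGrid = field(default_factory=WTPGrid.qaly_default)
    complete_case: bool = False
    include_categories: bool = False

    def __post_init__(self):
        if self.perspective not in ("societal", "payer"):
            raise ValueError(f"unknown perspective {self.perspective!r}")
        if self.effect not in ("qaly", "dfd"):
            raise ValueError(f"unknown effect measure {self.effect!r}")
        if self.perspective == "payer" and "sick_days_T0" in self.covariates:
            raise ValueError(
                "payer perspective excludes baseline sick days from covariates"
            )


def make_scenario(name: str, include_categories: bool = False) -> ScenarioConfig:
    """The four standard scenarios."""
    if name == "base_societal":
        return ScenarioConfig("base_societal",
                              include_categories=include_categories)
    if name == "payer":
        covs = tuple(c for c in BASE_COVARIATES if c != "sick_days_T0")
        return ScenarioConfig("payer", perspective="payer", covariates=covs)
    if name == "complete_case":
        return ScenarioConfig("complete_case", complete_case=True)
    if name == "dfd":
        return ScenarioConfig("dfd", effect="dfd", grid=WTPGrid.dfd_default())
    raise ValueError(f"unknown scenario {name!r}")


@dataclass(frozen=True)
class SubgroupDef:
    """Post-hoc subpopulation split (reduced covariate set)."""

    variable: str
    levels: tuple | None = None  # None -> all observed levels

    _ALLOWED = ("gender", "depression_history", "addiction",
                "mini_depression_T1")

    def __post_init__(self):
        if self.variable not in self._ALLOWED:
            raise ValueError(
                f"subgroup variable must be one of {self._ALLOWED}"
            )


@dataclass
class ScenarioResult:
    scenario: ScenarioConfig
    estimates: pd.DataFrame       # tidy model results, Table-2 layout
    icers: pd.DataFrame           # unadjusted ICERs per comparison
    ceacs: dict[str, pd.DataFrame]  # comparison -> (lambda, est, p, prob)
    n_analysed: int
    m: int


# --------------------------------------------------------------------------
# outcome preparation

def prepare_outcomes(df: pd.DataFrame, table: UnitCostTable, cpi: CPISeries,
                     effect: str = "qaly", perspective: str = "societal"
                     ) -> pd.DataFrame:
    """Attach per-participant ``effect`` and ``cost`` columns."""
    out = df.copy()
    if effect == "qaly":
        series = out[[f"eq5d_index_{t}" for t in schema.TIMEPOINTS]].to_numpy()
        out["effect"] = qaly_auc(series)
    else:
        series = out[[f"phq9_{t}" for t in schema.TIMEPOINTS]].to_numpy()
        out["effect"] = dfd_auc(series)
    bundle = compute_cost_bundle(out, table, cpi)
    out["cost"] = bundle[perspective].to_numpy()
    for col in ("direct", "informal_care", "indirect"):
        out[f"cost_{col}"] = bundle[col].to_numpy()
    return out


def _complete_case_mask(df: pd.DataFrame) -> pd.Series:
    """Participants with 12-month societal costs AND QALYs observed."""
    eq_cols = [f"eq5d_{t}" for t in schema.TIMEPOINTS]
    cost_cols = [f"{cat}_{t}" for t in FOLLOWUP
                 for cat in schema.RESOURCE_CATEGORIES]
    cost_cols += [f"sick_days_{t}" for t in FOLLOWUP]
    cost_cols += [f"informal_care_hours_{t}" for t in FOLLOWUP]
    return df[eq_cols + cost_cols].notna().all(axis=1)


# --------------------------------------------------------------------------
# CEAC

def _pool_arm(fits: list, arm: str):
    """Pooled (estimate, se, p) for one arm across per-imputation fits."""
    pooled = pool_fit_results(fits, arm)
    if pooled is None:
        return None
    return pooled.estimate, pooled.se, pooled.p


def ceac(frames: list[pd.DataFrame], grid: WTPGrid,
         covariates=BASE_COVARIATES, comparisons=COMPARISONS
         ) -> dict[str, pd.DataFrame]:
    """CEACs by net-benefit regression over a WTP grid.

    ``frames`` are completed datasets (one per imputation) that already
    carry ``effect`` and ``cost`` columns.  For each λ the NBR is
    fitted per imputation, pooled by Rubin's rules, and converted with
    the half-p rule.
    """
    spec = ModelSpec("net_benefit", covariates=tuple(covariates))
    rows: dict[str, list] = {c: [] for c in comparisons}
    for lam in grid.values:
        fits = []
        for f in frames:
            work = f
            work = work.assign(net_benefit=net_benefit(f["cost"], f["effect"], lam))
            fits.append(fit_effect_model(work, spec))
        for comp in comparisons:
            pooled = _pool_arm(fits, comp)
            if pooled is None:
                continue
            est, se, p = pooled
            rows[comp].append(
                {
                    "lambda": lam, "estimate": est, "se": se, "p": p,
                    "probability": ce_probability(est, p),
                }
            )
    return {c: pd.DataFrame(r) for c, r in rows.items() if r}


# --------------------------------------------------------------------------
# scenario driver

_FAMILY_FITTERS = {
    "linear": fit_effect_model,
    "gamma-log": fit_cost_model,
    "zi-gamma-log": fit_zi_cost_model,
}


def _pooled_rows(frames, outcome, family, covariates, label):
    spec = ModelSpec(outcome, family=family, covariates=tuple(covariates))
    fitter = _FAMILY_FITTERS[family]
    fits = [fitter(f, spec) for f in frames]
    rows = []
    for comp in COMPARISONS:
        pooled = [f.arm_estimates[comp] for f in fits
                  if comp in f.arm_estimates]
        if not pooled:
            continue
        if len(pooled) == 1:
            e = pooled[0]
            ci_low, ci_high = e.ci()
            est, se, p, dfv = e.estimate, e.se, e.p, e.df
        else:
            pe = rubin_pool(pooled)
            est, se, p, dfv = pe.estimate, pe.se, pe.p, pe.df
            ci_low, ci_high = pe.ci_low, pe.ci_high
        rows.append(
            {
                "outcome": label, "family": family, "comparison": comp,
                "estimate": est, "se": se, "ci_low": ci_low,
                "ci_high": ci_high, "p": p, "df": dfv,
                "method": fits[0].method, "m": len(pooled),
            }
        )
    return rows


def _unadjusted_icers(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Raw arm-mean ICERs on across-imputation averaged outcomes."""
    eff = np.mean([f["effect"].to_numpy() for f in frames], axis=0)
    cost = np.mean([f["cost"].to_numpy() for f in frames], axis=0)
    arm = frames[0]["arm"].to_numpy()
    means = {
        a: (float(cost[arm == a].mean()), float(eff[arm == a].mean()))
        for a in ARMS
    }
    rows = []
    for comp in COMPARISONS:
        dc = means[comp][0] - means["none"][0]
        de = means[comp][1] - means["none"][1]
        res = icer(dc, de)
        rows.append(
            {
                "comparison": comp, "mean_cost_ref": means["none"][0],
                "mean_cost": means[comp][0], "mean_effect_ref": means["none"][1],
                "mean_effect": means[comp][1], "delta_cost": res.delta_cost,
                "delta_effect": res.delta_effect, "icer": res.icer,
                "classification": res.classification,
            }
        )
    return pd.DataFrame(rows)


#: Cost categories modelled one-by-one (zero-inflated gamma).
SINGLE_CATEGORY_OUTCOMES = tuple(schema.RESOURCE_CATEGORIES)


def run_scenario(stack: ImputationStack, scenario: ScenarioConfig,
                 table: UnitCostTable, cpi: CPISeries) -> ScenarioResult:
    """Full decision-analytic bundle for one scenario.

    Unadjusted ICERs from raw arm means, adjusted mixed models for cost
    and effect, optional per-category two-part models, and CEACs over
    the scenario's WTP grid.
    """
    if scenario.complete_case:
        base = stack.original if stack.original is not None else stack.datasets[0]
        mask = _complete_case_mask(base.df)
        if int(mask.sum()) == 0:
            raise ValueError("complete-case scenario: no eligible participants")
        frames_raw = [base.df.loc[mask].reset_index(drop=True)]
    else:
        frames_raw = [d.df for d in stack.datasets]

    frames = [
        prepare_outcomes(f, table, cpi, scenario.effect, scenario.perspective)
        for f in frames_raw
    ]

    est_rows = []
    cost_label = f"total_cost_{scenario.perspective}"
    est_rows += _pooled_rows(frames, "cost", "gamma-log",
                             scenario.covariates, cost_label)
    est_rows += _pooled_rows(frames, "cost_direct", "gamma-log",
                             scenario.covariates, "direct_cost")
    est_rows += _pooled_rows(frames, "effect", "linear",
                             scenario.covariates, scenario.effect)
    if scenario.include_categories:
        for cat in SINGLE_CATEGORY_OUTCOMES:
            for f in frames:
                f[f"{cat}_cost"] = sum(
                    f[f"{cat}_{t}"].to_numpy(dtype=float) for t in FOLLOWUP
                )
            covs = tuple(
                c for c in scenario.covariates
                if (cat != "nursing_care_hour"
                    or c not in ("pregnancy", "breastfeeding"))
            )
            est_rows += _pooled_rows(frames, f"{cat}_cost", "zi-gamma-log",
                                     covs, cat)
        est_rows += _pooled_rows(frames, "cost_indirect", "zi-gamma-log",
                                 scenario.covariates, "indirect_cost")

    estimates = pd.DataFrame(est_rows)
    icers = _unadjusted_icers(frames)
    curves = ceac(frames, scenario.grid, scenario.covariates)
    for comp in curves:
        curves[comp].insert(0, "comparison", comp)
        curves[comp].insert(0, "scenario", scenario.name)
    return ScenarioResult(
        scenario=scenario, estimates=estimates, icers=icers, ceacs=curves,
        n_analysed=len(frames[0]), m=len(frames),
    )


def run_subgroup(stack: ImputationStack, subgroup: SubgroupDef,
                 scenario: ScenarioConfig, table: UnitCostTable,
                 cpi: CPISeries) -> dict[object, ScenarioResult]:
    """Scenario analysis per level of a splitting variable.

    Each imputed dataset is split on its own (possibly imputed) value
    of the variable; the reduced covariate set applies (pregnancy,
    breastfeeding and living situation dropped, city size binarised),
    minus the splitting variable itself.
    """
    covs = tuple(c for c in SUBGROUP_COVARIATES if c != subgroup.variable)
    sub_scenario = dc_replace(scenario, covariates=covs,
                              include_categories=False)
    base = stack.original if stack.original is not None else stack.datasets[0]
    levels = subgroup.levels
    if levels is None:
        obs = base.df[subgroup.variable].dropna().unique()
        levels = tuple(sorted(obs))
    results: dict[object, ScenarioResult] = {}
    for level in levels:
        sub_frames = []
        for d in stack.datasets:
            sel = d.df[subgroup.variable] == level
            if sel.any():
                sub_frames.append(
                    TrialDataset(d.df.loc[sel].reset_index(drop=True),
                                 d.config, d.schema_version)
                )
        n_min = min((len(d.df) for d in sub_frames), default=0)
        arms_ok = sub_frames and all(
            set(d.df["arm"]) == set(ARMS) for d in sub_frames
        )
        if not sub_frames or n_min < 3 * len(covs) or not arms_ok:
            warnings.warn(
                f"subgroup {subgroup.variable}={level!r} empty or too small "
                "to fit the adjusted models; skipped",
                stacklevel=2,
            )
            continue
        sub_stack = ImputationStack(
            datasets=sub_frames, methods=stack.methods,
            iterations=stack.iterations, seed=stack.seed,
            original=None,
        )
        try:
            results[level] = run_scenario(sub_stack, sub_scenario, table, cpi)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"subgroup {subgroup.variable}={level!r} analysis failed "
                f"({exc}); skipped", stacklevel=2,
            )
    return results


def plot_ceac(curves: dict[str, pd.DataFrame], path, title: str = "") -> None:
    """Line plot of cost-effectiveness probability over the WTP grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for comp, frame in curves.items():
        ax.plot(frame["lambda"], frame["probability"], marker="o",
                label=f"{comp} vs none")
    ax.set_xlabel("willingness to pay (€ per effect unit)")
    ax.set_ylabel("probability of cost-effectiveness")
    ax.set_ylim(0, 1)
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
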