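"""Adjusted models and Rubin pooling.

Families
--------
* linear (QALYs, DFDs, net benefit): linear mixed model with random
  intercepts for practices nested in study centres, REML.
* gamma-log (cost aggregates): gamma GLMM with log link, fitted by
  penalised quasi-likelihood (iterated working-response LMM; for the
  log link the gamma IRLS weights are constant, so each PQL step is an
  unweighted nested LMM).  If the PQL loop fails to converge the
  documented fallback is a gamma GLM with practice-clustered robust
  covariance, tagged in the result.
* zi-gamma-log (single cost categories, indirect costs): two-part
  model — logistic occurrence, gamma-log intensity on the positives —
  with the marginal arm effect combined by the delta method.

All arm contrasts are intervention − no-feedback; Wald tests use a t
reference with residual degrees of freedom.  Pooling across imputations
follows Rubin's rules with Barnard–Rubin adjusted degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import t as t_dist

from ._lmm import NestedLMMFit, fit_nested_lmm
from .schema import ARMS, CATEGORICAL_COVARIATES

__all__ = [
    "BASE_COVARIATES",
    "SUBGROUP_COVARIATES",
    "ModelSpec",
    "FitResult",
    "PooledEstimate",
    "build_design",
    "fit_effect_model",
    "fit_cost_model",
    "fit_zi_cost_model",
    "rubin_pool",
    "baseline_balance",
]

#: Fixed covariates of the adjusted models (base case): sociodemographics,
#: depression risk factors, baseline scores and baseline service use.
BASE_COVARIATES = (
    "age",
    "gender",
    "education_ge10y",
    "city_size",
    "living_situation",
    "eq5d_index_T0",
    "phq9_T0",
    "depression_history",
    "pregnancy",
    "breastfeeding",
    "inpatient_days_T0",
    "gp_visits_T0",
    "medication_count_T0",
    "sick_days_T0",
)

#: Reduced set for subpopulation analyses: covariates with too few
#: observations per stratum dropped, city size binarised.
SUBGROUP_COVARIATES = (
    "age",
    "gender",
    "education_ge10y",
    "city_size_binary",
    "eq5d_index_T0",
    "phq9_T0",
    "depression_history",
    "inpatient_days_T0",
    "gp_visits_T0",
    "medication_count_T0",
    "sick_days_T0",
)

_ZERO_COST_REPLACEMENT = 0.50  # € substituted for exact-zero gamma outcomes


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one adjusted model."""

    outcome: str
    family: str = "linear"  # linear | gamma-log | zi-gamma-log
    covariates: tuple[str, ...] = BASE_COVARIATES
    random_effects: bool = True
    reml: bool = True

    def __post_init__(self):
        if self.family not in ("linear", "gamma-log", "zi-gamma-log"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class ArmEstimate:
    estimate: float
    se: float
    df: float
    p: float

    @property
    def variance(self) -> float:
        return self.se ** 2

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        half = t_dist.ppf(0.5 + level / 2.0, self.df) * self.se
        return self.estimate - half, self.estimate + half


@dataclass
class FitResult:
    """One fitted model: arm contrasts plus metadata."""

    spec: ModelSpec
    arm_estimates: dict[str, ArmEstimate]
    method: str                     # e.g. "nested-lmm-reml", "pql-gamma", ...
    converged: bool
    n_obs: int
    variance_components: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    params: pd.Series | None = None

    def ratio(self, arm: str) -> float:
        """exp(coefficient) — cost ratio on the response scale."""
        return float(np.exp(self.arm_estimates[arm].estimate))


@dataclass
class PooledEstimate:
    """Rubin-pooled coefficient across M imputations."""

    estimate: float        # pooled Q-bar
    within: float          # W-bar
    between: float         # B
    total: float           # T = W + (1 + 1/M) B
    m: int
    df: float              # Barnard–Rubin adjusted df
    p: float
    ci_low: float
    ci_high: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total))


# --------------------------------------------------------------------------
# design construction (deterministic column order, no formula machinery)

def build_design(df: pd.DataFrame, covariates=BASE_COVARIATES,
                 include_arms: bool = True):
    """Fixed-effects design matrix: intercept, arm dummies, covariates.

    Categorical covariates are dummy-coded against their first category
    (gender reference: female).  Levels absent from the data are
    dropped and reported so callers can flag them.  ``city_size_binary``
    encodes large city (levels 3–4) vs small.
    """
    cols: list[np.ndarray] = [np.ones(len(df))]
    names: list[str] = ["intercept"]
    dropped: list[str] = []
    if include_arms:
        for arm in ARMS[1:]:
            cols.append((df["arm"] == arm).to_numpy(dtype=float))
            names.append(f"arm[{arm}]")
    for cov in covariates:
        if cov == "city_size_binary":
            cols.append((df["city_size"].to_numpy(dtype=float) >= 3).astype(float))
            names.append(cov)
        elif cov in CATEGORICAL_COVARIATES:
            levels = CATEGORICAL_COVARIATES[cov]
            present = set(df[cov].unique())
            for level in levels[1:]:
                if level in present:
                    cols.append((df[cov] == level).to_numpy(dtype=float))
                    names.append(f"{cov}[{level}]")
                else:
                    dropped.append(f"{cov}[{level}]")
        else:
            v = df[cov].to_numpy(dtype=float)
            if np.any(np.isnan(v)):
                raise ValueError(f"covariate {cov!r} has missing values")
            cols.append(v)
            names.append(cov)
    X = np.column_stack(cols)
    return X, names, dropped


def _drop_collinear(X: np.ndarray, names: list[str]):
    """Drop trailing columns that are numerically collinear (QR pivot-free)."""
    keep = [0]
    for j in range(1, X.shape[1]):
        sub = X[:, keep + [j]]
        if np.linalg.matrix_rank(sub) > len(keep):
            keep.append(j)
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    return X[:, keep], [names[j] for j in keep], dropped


def _arm_estimates_from_lmm(fit: NestedLMMFit, names: list[str]
                            ) -> dict[str, ArmEstimate]:
    out = {}
    p = fit.pvalues()
    for arm in ARMS[1:]:
        name = f"arm[{arm}]"
        if name not in names:
            continue
        j = names.index(name)
        out[arm] = ArmEstimate(
            float(fit.beta[j]), float(fit.se[j]), float(fit.df_resid),
            float(min(max(p[j], np.finfo(float).tiny), 1.0)),
        )
    return out


# --------------------------------------------------------------------------
# model fits

def fit_effect_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Linear mixed model for effects (QALYs, DFDs, net benefit)."""
    y = df[spec.outcome].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError(f"outcome {spec.outcome!r} has missing values")
    X, names, dropped = build_design(df, spec.covariates)
    X, names, collinear = _drop_collinear(X, names)
    warns = [f"empty level dropped: {d}" for d in dropped]
    warns += [f"collinear column dropped: {d}" for d in collinear]
    if spec.random_effects:
        fit = fit_nested_lmm(y, X, df["centre_id"].to_numpy(),
                             df["practice_id"].to_numpy(), names=names,
                             reml=spec.reml)
        vc = {"centre": fit.var_centre, "practice": fit.var_practice,
              "residual": fit.sigma2}
        if fit.singular:
            warns.append("variance component estimated at zero")
        return FitResult(
            spec=spec, arm_estimates=_arm_estimates_from_lmm(fit, names),
            method="nested-lmm-reml" if spec.reml else "nested-lmm-ml",
            converged=fit.converged, n_obs=fit.n_obs,
            variance_components=vc, warnings=warns,
            params=pd.Series(fit.beta, index=names),
        )
    res = sm.OLS(y, X).fit()
    ests = {}
    for arm in ARMS[1:]:
        j = names.index(f"arm[{arm}]")
        ests[arm] = ArmEstimate(float(res.params[j]), float(res.bse[j]),
                                float(res.df_resid), float(res.pvalues[j]))
    return FitResult(spec=spec, arm_estimates=ests, method="ols",
                     converged=True, n_obs=len(y), warnings=warns,
                     params=pd.Series(res.params, index=names))


def _pql_gamma(y, X, centre, practice, names, max_iter=30, tol=1e-6):
    """PQL loop for the gamma log-link GLMM (constant IRLS weights).

    Full working-response steps with adaptive damping: the step is
    halved whenever the coefficient update grows instead of shrinking.
    With very heavy-tailed outcomes the fixed point can still fail to
    stabilise, in which case the caller falls back to the tagged
    cluster-robust gamma GLM.
    """
    cc = pd.factorize(centre, sort=True)[0]
    pc = pd.factorize(practice, sort=True)[0]
    eta = np.log(np.maximum(y, 1e-6))
    beta_old = None
    delta_prev = np.inf
    damp = 1.0
    fit = None
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30, 30))
        z = eta + (y - mu) / mu
        fit = fit_nested_lmm(z, X, centre, practice, names=names, reml=True)
        eta = (1.0 - damp) * eta + damp * fit.fitted(X, cc, pc)
        if beta_old is not None:
            delta = np.max(np.abs(fit.beta - beta_old))
            if delta < tol:
                return fit, True
            if delta > delta_prev:
                damp = max(damp * 0.5, 0.125)
            delta_prev = delta
        beta_old = fit.beta
    return fit, False


def fit_cost_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Gamma log-link mixed model for strictly positive cost aggregates.

    Exact zeros are replaced by €0.50 (half the smallest plausible
    unit); the number of affected rows is recorded, never silently
    dropped.
    """
    y = df[spec.outcome].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError(f"outcome {spec.outcome!r} has missing values")
    if np.any(y < 0):
        raise ValueError("costs must be non-negative")
    warns = []
    n_zero = int((y == 0).sum())
    if n_zero:
        y = np.where(y == 0, _ZERO_COST_REPLACEMENT, y)
        warns.append(f"{n_zero} zero-cost rows set to {_ZERO_COST_REPLACEMENT}")
    X, names, dropped = build_design(df, spec.covariates)
    X, names, collinear = _drop_collinear(X, names)
    warns += [f"empty level dropped: {d}" for d in dropped]
    warns += [f"collinear column dropped: {d}" for d in collinear]

    if spec.random_effects:
        try:
            fit, ok = _pql_gamma(y, X, df["centre_id"].to_numpy(),
                                 df["practice_id"].to_numpy(), names)
        except np.linalg.LinAlgError:
            fit, ok = None, False
        if ok:
            vc = {"centre": fit.var_centre, "practice": fit.var_practice,
                  "dispersion": fit.sigma2}
            return FitResult(
                spec=spec, arm_estimates=_arm_estimates_from_lmm(fit, names),
                method="pql-gamma", converged=True, n_obs=len(y),
                variance_components=vc, warnings=warns,
                params=pd.Series(fit.beta, index=names),
            )
        warns.append("PQL did not converge; gamma GLM with "
                     "practice-clustered covariance used")
    # documented fallback (and the non-clustered route)
    glm = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    if spec.random_effects:
        res = glm.fit(cov_type="cluster",
                      cov_kwds={"groups": pd.factorize(df["practice_id"])[0]})
        method = "glm-gamma-cluster-robust"
    else:
        res = glm.fit()
        method = "glm-gamma"
    ests = {}
    for arm in ARMS[1:]:
        name = f"arm[{arm}]"
        if name not in names:
            continue
        j = names.index(name)
        dfres = float(res.df_resid)
        pj = 2.0 * t_dist.sf(abs(res.params[j] / res.bse[j]), dfres)
        ests[arm] = ArmEstimate(float(res.params[j]), float(res.bse[j]),
                                dfres, float(pj))
    return FitResult(spec=spec, arm_estimates=ests, method=method,
                     converged=res.converged if hasattr(res, "converged") else True,
                     n_obs=len(y), warnings=warns,
                     params=pd.Series(res.params, index=names))


def fit_zi_cost_model(df: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Two-part (zero-inflated gamma) model for a single cost category.

    Occurrence: logistic regression of any positive cost (practice-
    clustered covariance).  Intensity: gamma-log model on the positives.
    The marginal arm effect on log E[Y] combines both parts at the
    covariate means, with a delta-method standard error.
    """
    y = df[spec.outcome].to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError(f"outcome {spec.outcome!r} has missing values")
    pos = y > 0
    warns = []
    gamma_spec = replace(spec, family="gamma-log")
    if pos.all():
        # degenerate: no zeros, collapses to the plain gamma fit
        res = fit_cost_model(df, gamma_spec)
        res.method = "two-part/" + res.method
        res.warnings.append("no zero outcomes; occurrence part skipped")
        return res
    X, names, dropped = build_design(df, spec.covariates)
    X, names, collinear = _drop_collinear(X, names)
    warns += [f"empty level dropped: {d}" for d in dropped]
    warns += [f"collinear column dropped: {d}" for d in collinear]

    # occurrence part
    for arm in ARMS:
        sel = (df["arm"] == arm).to_numpy()
        if sel.any() and (pos[sel].all() or (~pos[sel]).all()):
            warns.append(f"separation risk: outcome all-{'positive' if pos[sel].all() else 'zero'} in arm {arm}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        occ = sm.GLM(pos.astype(float), X, family=sm.families.Binomial())
        try:
            occ_res = occ.fit(
                cov_type="cluster",
                cov_kwds={"groups": pd.factorize(df["practice_id"])[0]},
                maxiter=200,
            )
        except Exception:  # perfect separation etc.
            occ_res = occ.fit_regularized(alpha=1e-4, L1_wt=0.0)
            warns.append("occurrence model regularised (separation)")

    # intensity part on positives
    pos_df = df.loc[pos]
    gamma_res = fit_cost_model(pos_df, gamma_spec)
    warns += gamma_res.warnings

    # marginal effect: log ratio = d(gamma coef) + log q1 - log q0 at x-bar
    xbar = X.mean(axis=0)
    for arm in ARMS[1:]:
        xbar[names.index(f"arm[{arm}]")] = 0.0
    delta = np.asarray(occ_res.params)
    cov_occ = np.asarray(occ_res.cov_params())
    ests = {}
    for arm in ARMS[1:]:
        name = f"arm[{arm}]"
        if name not in names or arm not in gamma_res.arm_estimates:
            continue
        j = names.index(name)
        x1 = xbar.copy()
        x1[j] = 1.0
        q0 = float(expit(xbar @ delta))
        q1 = float(expit(x1 @ delta))
        # d log q / d delta = (1 - q) x
        grad = (1.0 - q1) * x1 - (1.0 - q0) * xbar
        var_occ = float(grad @ cov_occ @ grad)
        g = gamma_res.arm_estimates[arm]
        est = g.estimate + np.log(q1) - np.log(q0)
        se = float(np.sqrt(g.variance + var_occ))
        dfres = float(min(g.df, occ_res.df_resid))
        p = float(2.0 * t_dist.sf(abs(est / se), dfres))
        ests[arm] = ArmEstimate(float(est), se, dfres, p)
    return FitResult(
        spec=spec, arm_estimates=ests,
        method="two-part/" + gamma_res.method,
        converged=gamma_res.converged, n_obs=len(y),
        variance_components=gamma_res.variance_components,
        warnings=warns,
    )


# --------------------------------------------------------------------------
# Rubin's rules

def rubin_pool(estimates, variances=None, df_com: float | None = None,
               level: float = 0.95) -> PooledEstimate:
    """Pool M estimates by Rubin's rules (Barnard–Rubin df).

    Accepts either a list of :class:`ArmEstimate` or parallel arrays of
    estimates and variances (then ``df_com`` gives the complete-data
    residual df).
    """
    if variances is None:
        ests = np.array([e.estimate for e in estimates], dtype=float)
        variances = np.array([e.variance for e in estimates], dtype=float)
        df_com = float(min(e.df for e in estimates))
    else:
        ests = np.asarray(estimates, dtype=float)
        variances = np.asarray(variances, dtype=float)
        if df_com is None:
            raise ValueError("df_com required with raw arrays")
    m = len(ests)
    if m < 2:
        raise ValueError("Rubin pooling needs M >= 2 fits")
    qbar = float(ests.mean())
    wbar = float(variances.mean())
    b = float(ests.var(ddof=1))
    total = wbar + (1.0 + 1.0 / m) * b
    if b <= 0 or total <= 0:
        df_adj = df_com
    else:
        lam = (1.0 + 1.0 / m) * b / total
        nu_old = (m - 1) / lam ** 2
        nu_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
        df_adj = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)
    se = np.sqrt(total)
    tstat = qbar / se if se > 0 else 0.0
    p = float(2.0 * t_dist.sf(abs(tstat), df_adj))
    half = t_dist.ppf(0.5 + level / 2.0, df_adj) * se
    return PooledEstimate(
        estimate=qbar, within=wbar, between=b, total=float(total), m=m,
        df=float(df_adj), p=min(max(p, np.finfo(float).tiny), 1.0),
        ci_low=float(qbar - half), ci_high=float(qbar + half),
    )


def pool_fit_results(fits: list[FitResult], arm: str) -> PooledEstimate | ArmEstimate | None:
    """Pool one arm contrast across per-imputation fits of the same spec.

    Fits with heterogeneous model specifications are rejected.  With a
    single fit the per-fit estimate is returned unchanged.
    """
    if len({f.spec for f in fits}) > 1:
        raise ValueError("cannot pool fits with heterogeneous model specs")
    ests = [f.arm_estimates[arm] for f in fits if arm in f.arm_estimates]
    if not ests:
        return None
    if len(ests) == 1:
        return ests[0]
    return rubin_pool(ests)


# --------------------------------------------------------------------------
# baseline balance diagnostics

BALANCE_VARIABLES = {
    "age": "continuous",
    "inpatient_days_T0": "continuous",
    "medication_count_T0": "continuous",
    "gp_visits_T0": "continuous",
    "eq5d_index_T0": "continuous",
    "eq_vas_T0": "continuous",
    "phq9_T0": "continuous",
    "insurance_plan": "binary",
    "education_ge10y": "binary",
    "gender": "categorical",
    "city_size": "categorical",
}


def baseline_balance(df: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Systematic baseline differences between arms, vs no feedback.

    Continuous variables: OLS on arm dummies; binary: logistic
    regression; non-binary categorical: multinomial logistic with a
    joint Wald test per arm contrast.  Returns one row per variable
    with a p-value per intervention arm.
    """
    variables = variables or BALANCE_VARIABLES
    a1 = (df["arm"] == ARMS[1]).to_numpy(dtype=float)
    a2 = (df["arm"] == ARMS[2]).to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), a1, a2])
    rows = []
    for var, kind in variables.items():
        if var not in df.columns:
            continue
        pvals = {}
        flag = ""
        if kind == "continuous":
            res = sm.OLS(df[var].to_numpy(dtype=float), X).fit()
            pvals = {ARMS[1]: res.pvalues[1], ARMS[2]: res.pvalues[2]}
        elif kind == "binary":
            yv = df[var].to_numpy(dtype=float)
            if len(np.unique(yv)) < 2:
                flag = "constant variable; contrast not fitted"
                pvals = {ARMS[1]: np.nan, ARMS[2]: np.nan}
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.Logit(yv, X).fit(disp=0)
                    pvals = {ARMS[1]: res.pvalues[1], ARMS[2]: res.pvalues[2]}
                except Exception:  # singular / separated permuted draws
                    flag = "logistic fit failed (separation)"
                    pvals = {ARMS[1]: np.nan, ARMS[2]: np.nan}
        else:  # categorical -> multinomial logistic, joint Wald per arm
            codes, levels = pd.factorize(df[var], sort=True)
            if len(levels) < 2:
                flag = "constant variable; contrast not fitted"
                pvals = {ARMS[1]: np.nan, ARMS[2]: np.nan}
            elif len(levels) == 2:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.Logit(codes.astype(float), X).fit(disp=0)
                    pvals = {ARMS[1]: res.pvalues[1], ARMS[2]: res.pvalues[2]}
                    flag = "binary in data; logistic used"
                except Exception:
                    flag = "logistic fit failed (separation)"
                    pvals = {ARMS[1]: np.nan, ARMS[2]: np.nan}
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = sm.MNLogit(codes, X).fit(disp=0, maxiter=200)
                except Exception:
                    res = None
                    flag = "multinomial fit failed"
                    pvals = {ARMS[1]: np.nan, ARMS[2]: np.nan}
                k = len(levels) - 1  # equations
                for ai, arm in ((1, ARMS[1]), (2, ARMS[2])):
                    if res is None:
                        break
                    R = np.zeros((k, 3 * k))
                    for eq in range(k):
                        R[eq, eq * 3 + ai] = 1.0
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            w = res.wald_test(R, scalar=True)
                        pvals[arm] = float(w.pvalue)
                    except Exception:
                        pvals[arm] = np.nan
                        flag = "Wald test failed"
        rows.append(
            {
                "variable": var,
                "test": kind,
                f"p_{ARMS[1]}": float(pvals.get(ARMS[1], np.nan)),
                f"p_{ARMS[2]}": float(pvals.get(ARMS[2], np.nan)),
                "note": flag,
            }
        )
    return pd.DataFrame(rows)
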