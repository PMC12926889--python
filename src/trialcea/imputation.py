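"""Missingness diagnostics and multiple imputation by chained equations.

The trial's outcome fields are imputed at the score level (EQ-5D-5L
index, PHQ-9 total, resource counts per window), not at the derived
QALY/cost level: outcomes are recomputed from imputed assessments, and
type invariants stay checkable.  Continuous and count variables use
predictive-mean matching (k = 5 nearest donors, type-1 matching), so
every imputed value is an observed value of the right type; the binary
MINI diagnosis uses a Bayesian logistic draw.  Companion columns (the
5-digit EQ-5D state, the nine PHQ-9 items) are copied from the matched
donor so the dataset stays internally consistent.

The predictor matrix holds all baseline covariates, the arm, practice
dummies (which span the nested centres) and the same variable at the
other follow-up waves — mirroring the MAR conditioning set of the
diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from . import schema
from .schema import ARMS, FOLLOWUP
from .synthetic_trial import TrialDataset

__all__ = [
    "MissingnessReport",
    "ImputationStack",
    "missingness_diagnostics",
    "mice_impute",
]

_PMM_K = 5
_RIDGE = 1e-8

#: Baseline predictors screened in the missingness regressions.
DIAGNOSTIC_PREDICTORS = (
    "non_native",
    "smoker",
    "addiction",
    "eq5d_index_T0",
    "phq9_T0",
    "gp_visits_T0",
)

#: Donor companion columns copied together with a PMM-imputed score.
_COMPANIONS = {
    **{f"eq5d_index_{t}": [f"eq5d_{t}"] for t in FOLLOWUP},
    **{f"phq9_{t}": schema.phq9_item_columns(t) for t in FOLLOWUP},
}


@dataclass
class MissingnessReport:
    fractions: pd.Series                 # per maskable variable
    pattern_counts: pd.Series            # per T1/T2/T3 block pattern
    regressions: dict[str, pd.DataFrame]  # outcome label -> OR table
    n: int

    @property
    def overall_fraction(self) -> float:
        return float(self.fractions.mean())


@dataclass
class ImputationStack:
    """M completed datasets plus imputation metadata."""

    datasets: list[TrialDataset]
    methods: dict[str, str]
    iterations: int
    seed: int
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    original: TrialDataset | None = None

    @property
    def m(self) -> int:
        return len(self.datasets)

    def frames(self) -> list[pd.DataFrame]:
        return [d.df for d in self.datasets]


# --------------------------------------------------------------------------
# diagnostics

def _or_table(y: np.ndarray, df: pd.DataFrame) -> pd.DataFrame:
    X = np.column_stack(
        [np.ones(len(df))]
        + [
            (1.0 - df["native_speaker"].to_numpy(dtype=float))
            if p == "non_native" else df[p].to_numpy(dtype=float)
            for p in DIAGNOSTIC_PREDICTORS
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    ci = res.conf_int()
    rows = []
    for j, p in enumerate(DIAGNOSTIC_PREDICTORS, start=1):
        rows.append(
            {
                "predictor": p,
                "odds_ratio": float(np.exp(res.params[j])),
                "ci_low": float(np.exp(ci[j, 0])),
                "ci_high": float(np.exp(ci[j, 1])),
                "p": float(res.pvalues[j]),
            }
        )
    return pd.DataFrame(rows)


def missingness_diagnostics(data: TrialDataset) -> MissingnessReport:
    """Describe the missingness and regress it on baseline predictors.

    Reports the missing fraction per outcome variable, the counts of
    follow-up block patterns, and logistic regressions of two
    indicators — missing QALY inputs (any EQ-5D wave) and missing cost
    inputs (any resource-use field) — on fully observed baseline
    variables only.
    """
    df = data.df
    maskable = [c for c in schema.MASKABLE_COLUMNS if c in df.columns]
    fractions = df[maskable].isna().mean()

    block = pd.DataFrame(
        {
            t: df[[c for c in schema.outcome_columns(t) if c != "mini_depression_T1"]]
            .isna().any(axis=1)
            for t in FOLLOWUP
        }
    )
    pattern = block.apply(
        lambda r: "".join("M" if v else "O" for v in r), axis=1
    )
    pattern_counts = pattern.value_counts().sort_index()

    regressions: dict[str, pd.DataFrame] = {}
    if fractions.sum() > 0:
        qaly_missing = df[[f"eq5d_{t}" for t in FOLLOWUP]].isna().any(axis=1)
        cost_cols = [
            f"{cat}_{t}" for t in FOLLOWUP
            for cat in list(schema.RESOURCE_CATEGORIES)
        ] + [f"sick_days_{t}" for t in FOLLOWUP]
        cost_missing = df[cost_cols].isna().any(axis=1)
        for label, y in (("qaly", qaly_missing), ("costs", cost_missing)):
            if 0 < y.sum() < len(y):
                regressions[label] = _or_table(y.to_numpy(dtype=float), df)
    return MissingnessReport(
        fractions=fractions, pattern_counts=pattern_counts,
        regressions=regressions, n=len(df),
    )


# --------------------------------------------------------------------------
# chained equations

def _base_predictor_matrix(df: pd.DataFrame) -> np.ndarray:
    """Fixed part of every conditional model: baseline + arm + practice."""
    cols = [np.ones(len(df))]
    for arm in ARMS[1:]:
        cols.append((df["arm"] == arm).to_numpy(dtype=float))
    for cov in schema.BASELINE_COVARIATES:
        if cov in schema.CATEGORICAL_COVARIATES:
            for level in schema.CATEGORICAL_COVARIATES[cov][1:]:
                cols.append((df[cov] == level).to_numpy(dtype=float))
        else:
            cols.append(df[cov].to_numpy(dtype=float))
    for cov in schema.BASELINE_USE:
        cols.append(df[cov].to_numpy(dtype=float))
    cols.append(df["eq5d_index_T0"].to_numpy(dtype=float))
    cols.append(df["phq9_T0"].to_numpy(dtype=float))
    # practice dummies span the nested centre effects as well
    practices = pd.factorize(df["practice_id"], sort=True)[0]
    n_pr = practices.max() + 1
    for j in range(1, n_pr):
        cols.append((practices == j).astype(float))
    return np.column_stack(cols)


def _same_variable_companions(col: str) -> list[str]:
    """The same score at the other follow-up waves."""
    for t in FOLLOWUP:
        if col.endswith(f"_{t}"):
            stem = col[: -len(t) - 1]
            return [f"{stem}_{u}" for u in FOLLOWUP if u != t]
    return []


def _bayes_lstsq(B: np.ndarray, D: np.ndarray, y: np.ndarray,
                 BtB: np.ndarray, Bty: np.ndarray,
                 rng: np.random.Generator):
    """Posterior draw of (beta, sigma) for the working linear model.

    B is the precomputed fixed block (observed-target rows), D the
    dynamic same-variable block; cross-products with B are reused.
    """
    n_obs = len(y)
    if D.shape[1]:
        BtD = B.T @ D
        XtX = np.block([[BtB, BtD], [BtD.T, D.T @ D]])
        Xty = np.concatenate([Bty, D.T @ y])
    else:
        XtX, Xty = BtB, Bty
    p = XtX.shape[0]
    XtX = XtX + _RIDGE * np.trace(XtX) / p * np.eye(p)
    L = np.linalg.cholesky(XtX)
    beta_hat = np.linalg.solve(L.T, np.linalg.solve(L, Xty))
    rss = float(y @ y - Xty @ beta_hat)
    nu = max(n_obs - p, 1)
    sigma2 = max(rss, 1e-12) / rng.chisquare(nu)
    z = rng.normal(size=p)
    beta_star = beta_hat + np.sqrt(sigma2) * np.linalg.solve(L.T, z)
    return beta_hat, beta_star


def _pmm_update(work: pd.DataFrame, col: str, obs: np.ndarray,
                B_all: np.ndarray, BtB: np.ndarray, Bty: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """One PMM step for ``col``; returns donor row indices (observed)."""
    mis = ~obs
    others = [c for c in _same_variable_companions(col) if c in work.columns]
    D_all = (work[others].to_numpy(dtype=float)
             if others else np.empty((len(work), 0)))
    y = work.loc[obs, col].to_numpy(dtype=float)
    beta_hat, beta_star = _bayes_lstsq(
        B_all[obs], D_all[obs], y, BtB, Bty, rng
    )
    X_obs = np.concatenate([B_all[obs], D_all[obs]], axis=1)
    X_mis = np.concatenate([B_all[mis], D_all[mis]], axis=1)
    eta_obs = X_obs @ beta_hat
    eta_mis = X_mis @ beta_star
    dist = np.abs(eta_mis[:, None] - eta_obs[None, :])
    k = min(_PMM_K, dist.shape[1])
    nearest = np.argpartition(dist, k - 1, axis=1)[:, :k]
    pick = nearest[np.arange(len(eta_mis)), rng.integers(0, k, len(eta_mis))]
    return np.flatnonzero(obs)[pick]


def _logistic_update(work: pd.DataFrame, col: str, obs: np.ndarray,
                     B_all: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bayesian logistic draw for a binary variable; returns 0/1 values."""
    mis = ~obs
    y = work.loc[obs, col].to_numpy(dtype=float)
    X = B_all[obs]
    if len(np.unique(y)) < 2:
        return np.full(int(mis.sum()), y[0] if len(y) else 0.0)
    # ridge-stabilised Newton iterations
    p = X.shape[1]
    beta = np.zeros(p)
    for _ in range(25):
        eta = X @ beta
        mu = expit(eta)
        W = np.maximum(mu * (1 - mu), 1e-6)
        H = (X * W[:, None]).T @ X + 1e-4 * np.eye(p)
        g = X.T @ (y - mu) - 1e-4 * beta
        step = np.linalg.solve(H, g)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    cov = np.linalg.inv(H)
    beta_star = rng.multivariate_normal(beta, cov, method="cholesky")
    p_mis = expit(B_all[mis] @ beta_star)
    return (rng.random(int(mis.sum())) < p_mis).astype(float)


def mice_impute(data: TrialDataset, m: int = 20, iterations: int = 10,
                seed: int | None = None, variables: list[str] | None = None
                ) -> ImputationStack:
    """Create ``m`` completed datasets by chained equations.

    Parameters
    ----------
    data : dataset with (possibly) missing outcome fields
    m : number of imputations (the analysis default is 20)
    iterations : burn-in sweeps over the variables per imputation
    seed : master seed; the imputation substream is derived from it
    variables : restrict imputation to this subset of score variables
        (default: every imputable score with missing values)
    """
    df = data.df
    for col in ("arm", "centre_id", "practice_id"):
        if df[col].isna().any():
            raise ValueError(f"design variable {col!r} has missing values")
    seed = data.config.seed if seed is None else seed
    candidates = variables or [
        c for c in schema.imputable_columns() if c in df.columns
    ]
    targets = [c for c in candidates if df[c].isna().any()]
    # ascending missing fraction: better-observed scores stabilise first
    targets.sort(key=lambda c: (float(df[c].isna().mean()), c))
    methods = {
        c: ("logistic" if c == "mini_depression_T1" else "pmm") for c in targets
    }

    if not targets:
        stack = [data.copy() for _ in range(m)]
        return ImputationStack(stack, methods, iterations, seed,
                               trace=pd.DataFrame(), original=data)

    B_all = _base_predictor_matrix(df)
    obs_masks = {c: df[c].notna().to_numpy() for c in targets}
    for c, mask in obs_masks.items():
        if not mask.any():
            raise ValueError(f"variable {c!r} has no observed values to draw from")
    pre = {}
    for c in targets:
        if methods[c] == "pmm":
            B = B_all[obs_masks[c]]
            y = df.loc[obs_masks[c], c].to_numpy(dtype=float)
            pre[c] = (B.T @ B, B.T @ y)

    ss = np.random.SeedSequence((int(seed), 2))  # imputation stage stream
    child_seeds = ss.spawn(m)
    completed = []
    trace_rows = []
    for mi in range(m):
        rng = np.random.default_rng(child_seeds[mi])
        work = df.copy()
        # initial fill: random draws from the observed margin
        for c in targets:
            obs = obs_masks[c]
            donors = np.flatnonzero(obs)
            take = rng.choice(donors, size=int((~obs).sum()), replace=True)
            _copy_from_donors(work, c, np.flatnonzero(~obs), take, df)
        for it in range(iterations):
            for c in targets:
                obs = obs_masks[c]
                mis_idx = np.flatnonzero(~obs)
                if methods[c] == "logistic":
                    vals = _logistic_update(work, c, obs, B_all, rng)
                    work.iloc[mis_idx, work.columns.get_loc(c)] = vals
                else:
                    BtB, Bty = pre[c]
                    donor_rows = _pmm_update(work, c, obs, B_all, BtB, Bty, rng)
                    _copy_from_donors(work, c, mis_idx, donor_rows, df)
                imp_vals = work.iloc[mis_idx][c].to_numpy(dtype=float)
                trace_rows.append(
                    {
                        "imputation": mi, "iteration": it, "variable": c,
                        "mean": float(imp_vals.mean()),
                        "var": float(imp_vals.var()),
                    }
                )
        completed.append(TrialDataset(work, data.config, data.schema_version))
    trace = pd.DataFrame(trace_rows)
    _warn_if_drifting(trace, iterations)
    return ImputationStack(completed, methods, iterations, seed,
                           trace=trace, original=data)


def _copy_from_donors(work: pd.DataFrame, col: str, mis_idx: np.ndarray,
                      donor_rows: np.ndarray, source: pd.DataFrame) -> None:
    """Write donor values for the score and its companion columns."""
    cols = [col] + [c for c in _COMPANIONS.get(col, []) if c in work.columns]
    for c in cols:
        work.iloc[mis_idx, work.columns.get_loc(c)] = (
            source[c].to_numpy()[donor_rows]
        )


def _warn_if_drifting(trace: pd.DataFrame, iterations: int) -> None:
    if trace.empty or iterations < 4:
        return
    half = iterations // 2
    for c, g in trace.groupby("variable"):
        by_iter = g.groupby("iteration")["mean"].mean()
        early, late = by_iter.iloc[:half], by_iter.iloc[half:]
        spread = by_iter.std()
        if spread > 0 and abs(late.mean() - early.mean()) > 3.0 * spread:
            warnings.warn(
                f"imputation chain for {c!r} may not have converged; "
                "inspect the trace", stacklevel=3,
            )
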