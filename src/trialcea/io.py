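"""CSV/YAML serialisation.

External data interface: a wide baseline CSV (design + baseline fields,
one row per participant) and a long CSV (one row per participant x
time point with the longitudinal assessments).  Imputation stacks are
written as one wide CSV per completed dataset plus a YAML manifest.
Floats are written with a fixed "%.10g" format so that re-running a
seeded pipeline reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema
from .costing import RESOURCE_CATEGORIES
from .imputation import ImputationStack
from .synthetic_trial import (
    ArmEffect,
    CostParams,
    StratumEffect,
    TrialConfig,
    TrialDataset,
)

__all__ = [
    "FLOAT_FORMAT",
    "write_csv",
    "write_dataset",
    "read_dataset",
    "write_stack",
    "read_stack",
    "config_to_yaml",
    "config_from_yaml",
]

FLOAT_FORMAT = "%.10g"

_BASELINE_COLS = (
    list(schema.DESIGN_COLUMNS)
    + list(schema.BASELINE_COVARIATES)
    + list(schema.BASELINE_USE)
    + ["eq_vas_T0"]
)

_LONG_VALUE_COLS = (
    ["eq5d_state", "eq5d_index", "phq9"]
    + [f"phq9_i{k}" for k in range(1, 10)]
    + list(RESOURCE_CATEGORIES)
    + ["sick_days", "informal_care_hours", "mini_depression"]
)


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def _to_long(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for t in schema.TIMEPOINTS:
        part = pd.DataFrame(
            {"participant_id": df["participant_id"], "time": t}
        )
        part["eq5d_state"] = df[f"eq5d_{t}"]
        part["eq5d_index"] = df[f"eq5d_index_{t}"]
        part["phq9"] = df[f"phq9_{t}"]
        for k in range(1, 10):
            part[f"phq9_i{k}"] = df[f"phq9_i{k}_{t}"]
        for cat in RESOURCE_CATEGORIES:
            col = f"{cat}_{t}"
            part[cat] = df[col] if col in df.columns else np.nan
        part["sick_days"] = (
            df[f"sick_days_{t}"] if t != "T0" else np.nan
        )
        part["informal_care_hours"] = (
            df[f"informal_care_hours_{t}"] if t != "T0" else np.nan
        )
        part["mini_depression"] = (
            df["mini_depression_T1"] if t == "T1" else np.nan
        )
        rows.append(part)
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["participant_id", "time"], kind="stable").reset_index(
        drop=True
    )


def write_dataset(data: TrialDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as baseline.csv + long.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df = data.df
    paths = {
        "baseline": write_csv(df[_BASELINE_COLS], out_dir / "baseline.csv"),
        "long": write_csv(_to_long(df), out_dir / "long.csv"),
    }
    return paths


def read_dataset(data_dir: str | Path, config: TrialConfig | None = None
                 ) -> TrialDataset:
    """Reconstruct the wide frame from baseline.csv + long.csv."""
    data_dir = Path(data_dir)
    base = pd.read_csv(data_dir / "baseline.csv")
    long = pd.read_csv(data_dir / "long.csv")
    wide = base.copy()
    for t in schema.TIMEPOINTS:
        sub = long[long["time"] == t].set_index("participant_id")
        sub = sub.loc[wide["participant_id"]]
        wide[f"eq5d_{t}"] = sub["eq5d_state"].to_numpy()
        wide[f"eq5d_index_{t}"] = sub["eq5d_index"].to_numpy()
        wide[f"phq9_{t}"] = sub["phq9"].to_numpy()
        for k in range(1, 10):
            wide[f"phq9_i{k}_{t}"] = sub[f"phq9_i{k}"].to_numpy()
        if t != "T0":
            for cat in RESOURCE_CATEGORIES:
                wide[f"{cat}_{t}"] = sub[cat].to_numpy()
            wide[f"sick_days_{t}"] = sub["sick_days"].to_numpy()
            wide[f"informal_care_hours_{t}"] = sub["informal_care_hours"].to_numpy()
        if t == "T1":
            wide["mini_depression_T1"] = sub["mini_depression"].to_numpy()
    return TrialDataset(wide, config or TrialConfig())


# --------------------------------------------------------------------------
# imputation stacks

def write_stack(stack: ImputationStack, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, d in enumerate(stack.datasets, start=1):
        write_csv(d.df, out_dir / f"imputed_{i:02d}.csv")
    if not stack.trace.empty:
        write_csv(stack.trace, out_dir / "trace.csv")
    manifest = {
        "m": stack.m,
        "iterations": stack.iterations,
        "seed": int(stack.seed),
        "methods": dict(stack.methods),
    }
    (out_dir / "stack.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=True)
    )
    return out_dir


def read_stack(stack_dir: str | Path, config: TrialConfig | None = None
               ) -> ImputationStack:
    stack_dir = Path(stack_dir)
    manifest = yaml.safe_load((stack_dir / "stack.yaml").read_text())
    datasets = []
    for i in range(1, manifest["m"] + 1):
        df = pd.read_csv(stack_dir / f"imputed_{i:02d}.csv")
        datasets.append(TrialDataset(df, config or TrialConfig()))
    trace_path = stack_dir / "trace.csv"
    trace = pd.read_csv(trace_path) if trace_path.exists() else pd.DataFrame()
    return ImputationStack(
        datasets=datasets, methods=manifest["methods"],
        iterations=manifest["iterations"], seed=manifest["seed"], trace=trace,
    )


# --------------------------------------------------------------------------
# configuration

def config_to_yaml(config: TrialConfig, path: str | Path | None = None) -> str:
    payload = {
        "n_per_arm": config.n_per_arm,
        "n_centres": config.n_centres,
        "n_practices": config.n_practices,
        "missing_rate_target": config.missing_rate_target,
        "seed": config.seed,
        "diverse_prob": config.diverse_prob,
        "arm_effects": {a: asdict(e) for a, e in config.arm_effects.items()},
        "cost_params": {c: asdict(p) for c, p in config.cost_params.items()},
    }
    if config.heterogeneity is not None:
        payload["heterogeneity"] = {
            "variable": config.heterogeneity.variable,
            "level": config.heterogeneity.level,
            "arm_effects": {
                a: asdict(e) for a, e in config.heterogeneity.arm_effects.items()
            },
        }
    text = yaml.safe_dump(payload, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_from_yaml(source: str | Path) -> TrialConfig:
    """Load a TrialConfig from a YAML string or file path."""
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        payload = yaml.safe_load(Path(source).read_text())
    else:
        payload = yaml.safe_load(source)
    payload = payload or {}
    kwargs = {
        k: payload[k]
        for k in ("n_per_arm", "n_centres", "n_practices",
                  "missing_rate_target", "seed", "diverse_prob")
        if k in payload
    }
    if "arm_effects" in payload:
        kwargs["arm_effects"] = {
            a: ArmEffect(**e) for a, e in payload["arm_effects"].items()
        }
    if "cost_params" in payload:
        kwargs["cost_params"] = {
            c: CostParams(**p) for c, p in payload["cost_params"].items()
        }
    if "heterogeneity" in payload and payload["heterogeneity"]:
        h = payload["heterogeneity"]
        kwargs["heterogeneity"] = StratumEffect(
            variable=h["variable"], level=h["level"],
            arm_effects={a: ArmEffect(**e) for a, e in h["arm_effects"].items()},
        )
    return TrialConfig(**kwargs)
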