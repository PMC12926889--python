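"""Costing: resource-use counts, sick days and informal-care hours → €.

All unit costs are inflated to the 2022 price year with a consumer price
index before being applied.  Two perspectives are assembled:

* societal — direct costs (healthcare services, medication, formal
  nursing care) + informal care + indirect costs (productivity losses
  from absenteeism, human capital approach);
* healthcare payer — direct costs only.

Intervention costs are never added (they are negligible by design of
the feedback interventions).  Baseline resource use enters the analysis
only as model covariates and is never costed into follow-up totals.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RESOURCE_CATEGORIES",
    "UnitCostTable",
    "CPISeries",
    "cpi_adjust",
    "cost_resource_use",
    "productivity_loss",
    "informal_care_cost",
    "assemble_perspective",
    "compute_cost_bundle",
]

#: Follow-up resource-use categories costed as count × unit cost.
RESOURCE_CATEGORIES = (
    "gp_visit",
    "specialist_visit",
    "psychotherapy_session",
    "psychiatric_contact",
    "non_physician",
    "inpatient_day",
    "medication_item",
    "nursing_care_hour",
)

#: Non-count valuation rows the table must also provide.
SPECIAL_CATEGORIES = ("sick_day", "informal_care_wage", "informal_care_nonwage")

REFERENCE_YEAR = 2022
FOLLOWUP_WINDOWS = ("T1", "T2", "T3")

PERSPECTIVES = ("societal", "payer")


class CPISeries:
    """Consumer price index by calendar year (strictly positive)."""

    def __init__(self, values: dict[int, float]):
        if not values:
            raise ValueError("CPI series is empty")
        if any(v <= 0 for v in values.values()):
            raise ValueError("CPI values must be strictly positive")
        self._values = {int(k): float(v) for k, v in values.items()}

    def __getitem__(self, year: int) -> float:
        try:
            return self._values[int(year)]
        except KeyError:
            raise KeyError(f"year {year} not in CPI series") from None

    def __contains__(self, year: int) -> bool:
        return int(year) in self._values

    def years(self) -> list[int]:
        return sorted(self._values)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"year": self.years(), "cpi": [self._values[y] for y in self.years()]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CPISeries":
        df = pd.read_csv(path)
        return cls(dict(zip(df["year"], df["cpi"])))


class UnitCostTable:
    """Rows of (category, unit cost €/unit, price year)."""

    def __init__(self, table: pd.DataFrame):
        required = {"category", "unit_cost", "price_year"}
        if not required.issubset(table.columns):
            raise ValueError(f"unit-cost table needs columns {sorted(required)}")
        if (table["unit_cost"] < 0).any():
            raise ValueError("unit costs must be non-negative")
        self._frame = table.reset_index(drop=True)
        self._by_cat = {
            r.category: (float(r.unit_cost), int(r.price_year))
            for r in table.itertuples(index=False)
        }

    @property
    def table(self) -> pd.DataFrame:
        return self._frame.copy()

    def categories(self) -> list[str]:
        return list(self._by_cat)

    def unit_cost(self, category: str, cpi: CPISeries | None = None,
                  to_year: int = REFERENCE_YEAR) -> float:
        if category not in self._by_cat:
            raise KeyError(f"unknown cost category: {category!r}")
        cost, year = self._by_cat[category]
        if cpi is None:
            return cost
        return cpi_adjust(cost, year, to_year, cpi)

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "UnitCostTable":
        return cls(pd.read_csv(path))


def cpi_adjust(amount: float, from_year: int, to_year: int, cpi: CPISeries) -> float:
    """Inflate/deflate ``amount`` from one price year to another."""
    return amount * cpi[to_year] / cpi[from_year]


def cost_resource_use(data: pd.DataFrame, table: UnitCostTable, cpi: CPISeries,
                      categories=RESOURCE_CATEGORIES) -> pd.DataFrame:
    """Per-participant, per-category € over the follow-up windows.

    ``data`` is the wide trial frame with complete (imputed) counts in
    columns ``<category>_T1..T3``.  Each category's cost is
    count × CPI-adjusted unit cost summed over T1–T3.
    """
    out = pd.DataFrame(index=data.index)
    for cat in categories:
        unit = table.unit_cost(cat, cpi)
        counts = sum(
            data[f"{cat}_{w}"].to_numpy(dtype=float) for w in FOLLOWUP_WINDOWS
        )
        if np.any(np.isnan(counts)):
            raise ValueError(f"missing counts for category {cat!r}; impute first")
        if np.any(counts < 0):
            raise ValueError(f"negative counts for category {cat!r}")
        out[cat] = counts * unit
    return out


def productivity_loss(sick_days, gross_labour_cost_per_day: float):
    """Indirect cost of absenteeism (human capital approach)."""
    days = np.asarray(sick_days, dtype=float)
    if np.any(days < 0):
        raise ValueError("sick days must be non-negative")
    if gross_labour_cost_per_day < 0:
        raise ValueError("gross labour cost must be non-negative")
    out = days * gross_labour_cost_per_day
    return float(out) if out.ndim == 0 else out


def informal_care_cost(hours, wage_rate: float, nonwage_rate: float = 0.0):
    """Informal care valued at a professional substitute's gross labour
    cost per hour (replacement cost approach): (wage + non-wage) × hours."""
    h = np.asarray(hours, dtype=float)
    if np.any(h < 0):
        raise ValueError("informal care hours must be non-negative")
    if wage_rate < 0 or nonwage_rate < 0:
        raise ValueError("hourly rates must be non-negative")
    out = h * (wage_rate + nonwage_rate)
    return float(out) if out.ndim == 0 else out


def assemble_perspective(direct: float, informal: float, indirect: float,
                         perspective: str):
    """Total cost under a perspective.

    societal = direct + informal care + indirect; payer = direct only.
    Intervention costs are never part of any perspective.
    """
    if perspective == "societal":
        return direct + informal + indirect
    if perspective == "payer":
        return direct
    raise ValueError(f"unknown perspective: {perspective!r}")


def compute_cost_bundle(data: pd.DataFrame, table: UnitCostTable,
                        cpi: CPISeries) -> pd.DataFrame:
    """Full per-participant cost bundle over follow-up.

    Returns a frame with one column per direct category, plus
    ``direct``, ``informal_care``, ``indirect``, ``societal`` and
    ``payer`` totals (all in 2022 €).
    """
    bundle = cost_resource_use(data, table, cpi)
    bundle.insert(0, "participant_id", data["participant_id"].to_numpy())
    bundle["direct"] = bundle[list(RESOURCE_CATEGORIES)].sum(axis=1)

    sick = sum(data[f"sick_days_{w}"].to_numpy(dtype=float) for w in FOLLOWUP_WINDOWS)
    hours = sum(
        data[f"informal_care_hours_{w}"].to_numpy(dtype=float)
        for w in FOLLOWUP_WINDOWS
    )
    if np.any(np.isnan(sick)) or np.any(np.isnan(hours)):
        raise ValueError("missing sick days / informal care hours; impute first")
    bundle["indirect"] = productivity_loss(sick, table.unit_cost("sick_day", cpi))
    bundle["informal_care"] = informal_care_cost(
        hours,
        table.unit_cost("informal_care_wage", cpi),
        table.unit_cost("informal_care_nonwage", cpi),
    )
    bundle["societal"] = assemble_perspective(
        bundle["direct"], bundle["informal_care"], bundle["indirect"], "societal"
    )
    bundle["payer"] = assemble_perspective(
        bundle["direct"], bundle["informal_care"], bundle["indirect"], "payer"
    )
    return bundle
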