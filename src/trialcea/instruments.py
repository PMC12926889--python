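"""Instrument scoring and effect measures.

Scores the EQ-5D-5L descriptive system against an additive value set,
sums the PHQ-9, and converts four-wave longitudinal scores into the two
effect measures used by the economic models:

* QALYs — area under the linearly interpolated EQ-5D-5L utility index
  over the follow-up, divided by an annual denominator;
* depression-free days (DFDs) — the PHQ-9 is interpolated linearly in
  continuous time, mapped through a piecewise-linear day-level
  probability of being depression free, and integrated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DIMENSIONS",
    "ValueSet",
    "EffectSeries",
    "SEVERITY_BANDS",
    "score_eq5d_index",
    "score_phq9",
    "phq9_severity",
    "qaly_auc",
    "dfd_probability",
    "dfd_auc",
]

#: EQ-5D-5L dimensions in digit order: mobility, self-care, usual
#: activities, pain/discomfort, anxiety/depression.
DIMENSIONS = ("MO", "SC", "UA", "PD", "AD")

#: Default reference days between consecutive assessments
#: (T0→T1 = 1 month, T1→T2 = 5 months, T2→T3 = 6 months).
REFERENCE_DAYS = (30, 150, 180)

#: Days in one year used to convert utility-days into QALYs.
QALY_DENOMINATOR = 365.0


class ValueSet:
    """Additive EQ-5D-5L value set: index = 1 − Σ decrement(dimension, level).

    Level-1 decrements are zero by construction, so state 11111 scores
    exactly 1.0.  The minimum over all 3125 states is ``floor()``.
    """

    def __init__(self, decrements: pd.DataFrame, label: str = "unlabelled"):
        required = {"dimension", "level", "decrement"}
        if not required.issubset(decrements.columns):
            raise ValueError(f"value set table needs columns {sorted(required)}")
        self.label = label
        tab = np.zeros((5, 6))  # [dim, level]; level index 1..5
        for row in decrements.itertuples(index=False):
            d = DIMENSIONS.index(row.dimension)
            tab[d, int(row.level)] = float(row.decrement)
        if np.any(tab[:, 1] != 0.0):
            raise ValueError("level-1 decrements must be zero (index(11111) = 1)")
        self._tab = tab
        self._frame = decrements.reset_index(drop=True)

    @property
    def table(self) -> pd.DataFrame:
        return self._frame.copy()

    def floor(self) -> float:
        """Worst attainable index (all dimensions at level 5)."""
        return 1.0 - float(self._tab[:, 5].sum())

    def index(self, state) -> float | np.ndarray:
        return score_eq5d_index(state, self)

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "ValueSet":
        return cls(pd.read_csv(path), label=label or str(path))


def _split_digits(state: np.ndarray) -> np.ndarray:
    """(n,) int states like 21121 -> (n, 5) digit array."""
    digits = np.stack(
        [(state // 10 ** (4 - k)) % 10 for k in range(5)], axis=-1
    )
    return digits


def score_eq5d_index(state, vs: ValueSet):
    """Utility index of one or many 5-digit EQ-5D-5L states.

    Parameters
    ----------
    state : int, str or array-like of them; each digit must be in 1..5.
    vs : ValueSet
    """
    arr = np.asarray(state)
    scalar = arr.ndim == 0
    vals = np.atleast_1d(arr)
    if vals.dtype.kind in "UO":
        vals = np.array([int(v) for v in vals])
    vals = vals.astype(np.int64)
    digits = _split_digits(vals)
    if np.any((digits < 1) | (digits > 5)):
        bad = vals[np.any((digits < 1) | (digits > 5), axis=-1)][0]
        raise ValueError(f"invalid EQ-5D-5L state {bad}: each digit must be 1..5")
    dec = vs._tab[np.arange(5)[None, :], digits]
    out = 1.0 - dec.sum(axis=-1)
    return float(out[0]) if scalar else out


def score_phq9(items) -> int | np.ndarray:
    """Total PHQ-9 score: the sum of the nine item scores (each 0–3)."""
    arr = np.asarray(items)
    if arr.shape[-1] != 9:
        raise ValueError(f"PHQ-9 needs exactly 9 items, got {arr.shape[-1]}")
    if np.any(np.isnan(arr.astype(float))):
        raise ValueError("PHQ-9 items contain missing values")
    arr = arr.astype(np.int64)
    if np.any((arr < 0) | (arr > 3)):
        raise ValueError("PHQ-9 item scores must be in 0..3")
    total = arr.sum(axis=-1)
    return int(total) if total.ndim == 0 else total


#: Severity bands partitioning the 0–27 PHQ-9 range.
SEVERITY_BANDS = (
    ("none/minimal", 0, 4),
    ("mild", 5, 9),
    ("moderate", 10, 14),
    ("moderately severe", 15, 19),
    ("severe", 20, 27),
)


def phq9_severity(total: float) -> str:
    """Severity band label for a PHQ-9 total (fractional means allowed)."""
    if not 0 <= total <= 27:
        raise ValueError(f"PHQ-9 total {total} outside 0..27")
    for label, lo, hi in SEVERITY_BANDS:
        if lo <= total < hi + 1 or (hi == 27 and total == 27):
            return label
    raise AssertionError("unreachable: bands partition 0..27")


@dataclass
class EffectSeries:
    """Four-wave series of one participant's effect inputs.

    ``values`` are EQ-5D-5L indices (for QALYs) or PHQ-9 totals (for
    DFDs) at T0..T3; ``reference_days`` are the days between consecutive
    assessments.
    """

    participant_id: int
    values: tuple[float, float, float, float]
    reference_days: tuple[int, int, int] = REFERENCE_DAYS

    def __post_init__(self):
        if len(self.values) != 4:
            raise ValueError("EffectSeries needs exactly four values (T0..T3)")
        if len(self.reference_days) != 3:
            raise ValueError("reference_days needs exactly three segments")


def _check_complete(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError(
            "missing value in effect series: impute before computing AUC outcomes"
        )
    return arr


def qaly_auc(series, reference_days=REFERENCE_DAYS, denominator=QALY_DENOMINATOR):
    """QALYs as trapezoidal AUC of the utility index over follow-up.

    ``series`` may be an :class:`EffectSeries`, a length-4 sequence, or a
    2-D array (participants × 4) — the trapezoid is vectorised over rows.
    QALY = Σ_seg days_seg · (u_start + u_end) / 2 / denominator.
    """
    if isinstance(series, EffectSeries):
        reference_days = series.reference_days
        values = series.values
    else:
        values = series
    u = _check_complete(values)
    d = np.asarray(reference_days, dtype=float)
    auc = ((u[..., :-1] + u[..., 1:]) / 2.0 * d).sum(axis=-1)
    out = auc / float(denominator)
    return float(out) if np.ndim(out) == 0 else out


def dfd_probability(phq9):
    """Probability of a depression-free day given a PHQ-9 level.

    1 for scores of 5 or below, 0 for 15 or above, and the linear
    interpolation (15 − s)/10 in between; continuous at both knots.
    """
    arr = np.asarray(phq9, dtype=float)
    if np.any((arr < 0) | (arr > 27)):
        raise ValueError("PHQ-9 value outside 0..27")
    out = np.clip((15.0 - arr) / 10.0, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def _segment_dfd(p0: float, p1: float, days: float) -> float:
    """Exact ∫ f(s(t)) dt over one segment with s linear from p0 to p1.

    f is the piecewise-linear depression-free-day probability, so the
    composition is piecewise linear in t with breakpoints where s
    crosses 5 and 15; integrate trapezoids between breakpoints.
    """
    if days == 0:
        return 0.0
    ts = [0.0, days]
    if p1 != p0:
        for knot in (5.0, 15.0):
            t = days * (knot - p0) / (p1 - p0)
            if 0.0 < t < days:
                ts.append(t)
    ts = sorted(ts)
    total = 0.0
    for a, b in zip(ts[:-1], ts[1:]):
        sa = p0 + (p1 - p0) * a / days
        sb = p0 + (p1 - p0) * b / days
        fa = min(max((15.0 - sa) / 10.0, 0.0), 1.0)
        fb = min(max((15.0 - sb) / 10.0, 0.0), 1.0)
        total += (b - a) * (fa + fb) / 2.0
    return total


def dfd_auc(series, reference_days=REFERENCE_DAYS):
    """Depression-free days over follow-up (in days, range 0..Σ days).

    The PHQ-9 is assumed to change linearly between assessments; the
    day-level probability is integrated in closed form per segment.
    """
    if isinstance(series, EffectSeries):
        reference_days = series.reference_days
        values = series.values
    else:
        values = series
    s = _check_complete(values)
    if np.any((s < 0) | (s > 27)):
        raise ValueError("PHQ-9 value outside 0..27")
    d = np.asarray(reference_days, dtype=float)
    if s.ndim == 1:
        return sum(
            _segment_dfd(s[k], s[k + 1], d[k]) for k in range(len(d))
        )
    return np.array(
        [
            sum(_segment_dfd(row[k], row[k + 1], d[k]) for k in range(len(d)))
            for row in s
        ]
    )
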