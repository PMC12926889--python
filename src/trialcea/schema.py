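"""Column layout of the wide per-participant trial frame.

One row per participant.  Longitudinal fields carry a ``_T0..T3``
suffix; follow-up resource use is recorded per inter-assessment window
(T1 = month 0–1, T2 = months 1–6, T3 = months 6–12), so the windows
tile the year without overlap.
"""

from __future__ import annotations

from .costing import RESOURCE_CATEGORIES

ARMS = ("none", "gp", "gp_plus_patient")
TIMEPOINTS = ("T0", "T1", "T2", "T3")
FOLLOWUP = ("T1", "T2", "T3")

#: Months covered by each follow-up window (tiling the 12-month horizon).
WINDOW_MONTHS = {"T1": 1.0, "T2": 5.0, "T3": 6.0}

DESIGN_COLUMNS = ("participant_id", "arm", "centre_id", "practice_id")

#: Baseline sociodemographics and depression risk factors.
BASELINE_COVARIATES = (
    "age",
    "gender",
    "education_ge10y",
    "city_size",
    "living_situation",
    "insurance_plan",
    "native_speaker",
    "smoker",
    "depression_history",
    "addiction",
    "pregnancy",
    "breastfeeding",
)

#: Baseline healthcare service use (covariates only, never costed).
BASELINE_USE = (
    "gp_visits_T0",
    "inpatient_days_T0",
    "medication_count_T0",
    "sick_days_T0",
)

CATEGORICAL_COVARIATES = {
    "gender": ("female", "male", "diverse"),
    "city_size": (1, 2, 3, 4),
    "living_situation": ("alone", "partner", "family", "other"),
}


def phq9_item_columns(t: str) -> list[str]:
    return [f"phq9_i{k}_{t}" for k in range(1, 10)]


def outcome_columns(t: str) -> list[str]:
    """Post-baseline fields assessed at follow-up time point ``t``."""
    cols = [f"eq5d_{t}", f"eq5d_index_{t}", f"phq9_{t}", *phq9_item_columns(t)]
    cols += [f"{cat}_{t}" for cat in RESOURCE_CATEGORIES]
    cols += [f"sick_days_{t}", f"informal_care_hours_{t}"]
    if t == "T1":
        cols.append("mini_depression_T1")
    return cols


#: All fields eligible for the MAR missingness mechanism.
MASKABLE_COLUMNS = tuple(c for t in FOLLOWUP for c in outcome_columns(t))

#: Score-level variables entering chained-equation imputation, in a
#: deterministic order (companion columns — EQ-5D states, PHQ-9 items —
#: are carried along by the predictive-mean-matching donors).
def imputable_columns() -> list[str]:
    cols = []
    for t in FOLLOWUP:
        cols += [f"eq5d_index_{t}", f"phq9_{t}"]
    for t in FOLLOWUP:
        cols += [f"{cat}_{t}" for cat in RESOURCE_CATEGORIES]
        cols += [f"sick_days_{t}", f"informal_care_hours_{t}"]
    cols.append("mini_depression_T1")
    return cols
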