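"""Dyslipidemia cohort extraction: eligibility criteria and attrition log.

Entry is the first E78 (dyslipidemia) diagnosis.  Seven exclusion steps are
applied in a fixed order so attrition logs are comparable across runs:

1. no dyslipidemia diagnosis at all;
2. enrolled less than 6 months before entry (run-in);
3. no confirmatory dyslipidemia code in the half-year after entry
   (strictly after entry, up to entry + 6 months inclusive);
4. younger than 20 years at entry;
5. outcome on or before the entry date (prevalent disease);
6. statin prescription before entry (prevalent user);
7. observation period shorter than the model's minimum follow-up.

The observation period runs from entry to the earlier of the index date
(outcome onset) and the final dyslipidemia diagnosis.  An outcome occurring
after the final dyslipidemia code falls outside observation: the patient is
kept as a non-case censored at the final code.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dates import add_months_series, months_between, months_between_series
from .claims import ClaimsDatabase, CodeSet, CodeSystem
from .config import CodeConfig
from .matching import outcome_hits_frame


@dataclass(frozen=True)
class ModelSpec:
    model_id: str
    min_followup_months: int
    exposure_window_months: int

    def __post_init__(self) -> None:
        if self.min_followup_months != self.exposure_window_months:
            raise ValueError("follow-up minimum and exposure window must agree")


MODEL1 = ModelSpec("model1", 12, 12)
MODEL2 = ModelSpec("model2", 24, 24)
MODELS = {"model1": MODEL1, "model2": MODEL2}


@dataclass(frozen=True)
class AttritionStep:
    label: str
    n_excluded: int
    n_remaining: int


@dataclass
class AttritionLog:
    n_input: int
    steps: list[AttritionStep]

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "steps": [
                {"label": s.label, "n_excluded": s.n_excluded, "n_remaining": s.n_remaining}
                for s in self.steps
            ],
        }


STEP_LABELS = [
    "no dyslipidemia diagnosis",
    "run-in shorter than 6 months",
    "no confirmatory dyslipidemia diagnosis within 6 months",
    "younger than 20 years at entry",
    "outcome before first dyslipidemia diagnosis",
    "statin use before first dyslipidemia diagnosis",
    "observation period shorter than minimum follow-up",
]

COHORT_COLUMNS = [
    "patient_id",
    "sex",
    "entry_date",
    "age_at_entry",
    "last_dyslipidemia_date",
    "index_date",
    "index_channel",
    "observation_end",
    "observation_months",
    "duration_to_index",
]


def first_diagnosis_date(
    db: ClaimsDatabase, patient_id: str, code_set: CodeSet
) -> dt.date | None:
    """Earliest matching diagnosis date for one patient, or None."""
    ev = db.events_for(patient_id)
    ev = ev[ev["system"] == code_set.system.value]
    if len(ev):
        ev = ev[code_set.mask(ev["code"])]
    if not len(ev):
        return None
    return ev["date"].min().date()


def build_cohort(
    db: ClaimsDatabase, spec: ModelSpec, code_config: CodeConfig
) -> tuple[pd.DataFrame, AttritionLog]:
    """Apply the eligibility criteria, returning the cohort frame and log.

    The cohort frame has one row per retained patient (columns
    ``COHORT_COLUMNS``), sorted by patient_id; ``index_date`` is set only
    for cases whose outcome falls inside the observation period.
    """
    patients = db.patients
    n_input = len(patients)
    events = db.events

    dysl = events[events["system"] == CodeSystem.ICD10.value]
    if len(dysl):
        dysl = dysl[code_config.dyslipidemia.mask(dysl["code"])]
    per_pat = (
        dysl.groupby("patient_id")["date"].agg(["min", "max"]).rename(
            columns={"min": "entry_date", "max": "last_dyslipidemia_date"}
        )
        if len(dysl)
        else pd.DataFrame(columns=["entry_date", "last_dyslipidemia_date"])
    )

    work = patients.merge(per_pat, left_on="patient_id", right_index=True, how="left")
    work = work.sort_values("patient_id").reset_index(drop=True)

    steps: list[AttritionStep] = []
    keep = work["entry_date"].notna().to_numpy()

    def record(mask_keep: np.ndarray, label: str) -> np.ndarray:
        nonlocal keep
        excluded = int((keep & ~mask_keep).sum())
        keep = keep & mask_keep
        steps.append(AttritionStep(label, excluded, int(keep.sum())))
        return keep

    steps.append(
        AttritionStep(STEP_LABELS[0], int((~keep).sum()), int(keep.sum()))
    )

    entry = work["entry_date"]
    safe_entry = entry.fillna(work["enroll_start"])

    # 2: at least 6 months enrolled before entry
    run_in_ok = (
        months_between_series(work["enroll_start"], safe_entry) >= 6
    ) & (work["enroll_start"] <= safe_entry)
    record(run_in_ok, STEP_LABELS[1])

    # 3: confirmatory code in (entry, entry + 6 months]
    confirm_end = add_months_series(safe_entry, 6)
    dysl2 = dysl.merge(
        pd.DataFrame(
            {
                "patient_id": work["patient_id"],
                "_entry": safe_entry,
                "_cend": confirm_end,
            }
        ),
        on="patient_id",
        how="left",
    )
    confirmed_ids = set(
        dysl2.loc[
            (dysl2["date"] > dysl2["_entry"]) & (dysl2["date"] <= dysl2["_cend"]),
            "patient_id",
        ]
    )
    record(work["patient_id"].isin(confirmed_ids).to_numpy(), STEP_LABELS[2])

    # 4: age >= 20 at entry (completed years from birth year-month)
    age = months_between_series(work["birth_ym"], safe_entry) // 12
    record(age >= 20, STEP_LABELS[3])

    # 5: no outcome on or before entry
    hits = outcome_hits_frame(db, code_config)
    work = work.merge(hits, on="patient_id", how="left")
    has_prior_outcome = work["outcome_date"].notna() & (
        work["outcome_date"] <= safe_entry
    )
    record(~has_prior_outcome.to_numpy(), STEP_LABELS[4])

    # 6: no statin prescription strictly before entry
    statin_set = code_config.statins.as_code_set()
    rx = events[events["system"] == CodeSystem.ATC_EPHMRA.value]
    if len(rx):
        rx = rx[statin_set.mask(rx["code"])]
    rx2 = rx.merge(
        pd.DataFrame({"patient_id": work["patient_id"], "_entry": safe_entry}),
        on="patient_id",
        how="left",
    )
    prior_statin_ids = set(rx2.loc[rx2["date"] < rx2["_entry"], "patient_id"])
    record(~work["patient_id"].isin(prior_statin_ids).to_numpy(), STEP_LABELS[5])

    # 7: observation period >= minimum follow-up
    last_dysl = work["last_dyslipidemia_date"]
    idx_date = work["outcome_date"]
    in_obs = idx_date.notna() & last_dysl.notna() & (idx_date <= last_dysl)
    obs_end = last_dysl.copy()
    obs_end[in_obs] = idx_date[in_obs]
    obs_end = obs_end.fillna(safe_entry)
    obs_end = obs_end.where(obs_end >= safe_entry, safe_entry)
    obs_months = months_between_series(safe_entry, obs_end)
    record(obs_months >= spec.min_followup_months, STEP_LABELS[6])

    kept_idx = np.flatnonzero(keep)
    out = work.iloc[kept_idx].copy()
    out["age_at_entry"] = age[kept_idx]
    is_case = pd.Series(in_obs.to_numpy()[kept_idx], index=out.index)
    out["index_date"] = out["outcome_date"].where(is_case, pd.NaT)
    out["index_channel"] = out["outcome_channel"].where(is_case, None)
    out["observation_end"] = obs_end.iloc[kept_idx]
    out["observation_months"] = obs_months[kept_idx]
    dur = np.full(len(out), -1, dtype=int)
    case_rows = np.flatnonzero(is_case.to_numpy())
    if len(case_rows):
        dur[case_rows] = months_between_series(
            out["entry_date"].iloc[case_rows], out["index_date"].iloc[case_rows]
        )
    out["duration_to_index"] = dur
    out = out[COHORT_COLUMNS].reset_index(drop=True)
    return out, AttritionLog(n_input, steps)


__all__ = [
    "ModelSpec",
    "MODEL1",
    "MODEL2",
    "MODELS",
    "AttritionStep",
    "AttritionLog",
    "STEP_LABELS",
    "COHORT_COLUMNS",
    "first_diagnosis_date",
    "build_cohort",
    "months_between",
]
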