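"""Composite-outcome detection and risk-set sampling of matched controls.

The outcome (open-angle glaucoma onset) is a composite of three channels —
diagnosis codes H401/H406/H409, anti-glaucoma drug dispensing (S1E2), and
glaucoma surgery (K268); the index date is the earliest date across the
channels, with same-day ties broken by the fixed priority
diagnosis > drug > surgery.

Controls are sampled by risk-set (incidence-density) sampling: for each
case, candidates are cohort members of the same sex, within ±5 years of age
at entry and ±3 calendar months of entry, whose observation period reaches
at least the case's duration-to-index and who are outcome-free at that
duration.  A later case may serve as a control for an earlier one, and the
same person may be reused across sets ("sampling with replacement"); within
a set, up to ``max_controls`` distinct controls are drawn uniformly.
The case's calendar index date is applied unchanged to its controls.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dates import month_index_series
from .claims import ClaimsDatabase, CodeSystem
from .config import CodeConfig

CHANNELS = ("diagnosis", "drug", "surgery")  # tie-break priority order


@dataclass(frozen=True)
class OutcomeHit:
    patient_id: str
    index_date: dt.date
    channel: str


@dataclass(frozen=True)
class MatchingParams:
    max_controls: int = 10
    age_caliper_years: int = 5
    entry_caliper_months: int = 3
    seed: int = 0
    allow_future_cases: bool = True

    def __post_init__(self) -> None:
        if self.max_controls < 1:
            raise ValueError("max_controls must be >= 1")
        if self.age_caliper_years < 0 or self.entry_caliper_months < 0:
            raise ValueError("calipers must be >= 0")


@dataclass(frozen=True)
class MatchedSet:
    set_id: int
    case_id: str
    control_ids: tuple[str, ...]
    index_date: dt.date
    case_duration_months: int


@dataclass
class SamplingLog:
    n_cases: int
    n_sets: int
    dropped_cases: list[str] = field(default_factory=list)
    pool_sizes: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_sets": self.n_sets,
            "dropped_cases": self.dropped_cases,
            "pool_sizes": self.pool_sizes,
        }


def outcome_hits_frame(db: ClaimsDatabase, code_config: CodeConfig) -> pd.DataFrame:
    """Earliest composite-outcome hit per patient.

    Returns columns patient_id, outcome_date, outcome_channel (one row per
    patient with at least one qualifying event).
    """
    events = db.events
    parts = []
    channel_sets = {
        "diagnosis": (CodeSystem.ICD10, code_config.outcome_diagnosis),
        "drug": (CodeSystem.ATC_EPHMRA, code_config.outcome_drug),
        "surgery": (CodeSystem.JP_PROCEDURE, code_config.outcome_surgery),
    }
    for rank, channel in enumerate(CHANNELS):
        system, cs = channel_sets[channel]
        ev = events[events["system"] == system.value]
        if len(ev):
            ev = ev[cs.mask(ev["code"])]
        if len(ev):
            first = ev.groupby("patient_id")["date"].min().reset_index()
            first["outcome_channel"] = channel
            first["_rank"] = rank
            parts.append(first)
    if not parts:
        return pd.DataFrame(
            {
                "patient_id": pd.Series([], dtype=str),
                "outcome_date": pd.Series([], dtype="datetime64[ns]"),
                "outcome_channel": pd.Series([], dtype=object),
            }
        )
    allhits = pd.concat(parts, ignore_index=True)
    allhits = allhits.sort_values(["patient_id", "date", "_rank"], kind="stable")
    best = allhits.drop_duplicates("patient_id", keep="first")
    return best.rename(columns={"date": "outcome_date"})[
        ["patient_id", "outcome_date", "outcome_channel"]
    ].reset_index(drop=True)


def find_index_date(
    db: ClaimsDatabase, patient_id: str, code_config: CodeConfig
) -> OutcomeHit | None:
    """Earliest outcome across the three channels for one patient."""
    if not db.has_patient(patient_id):
        raise KeyError(f"unknown patient {patient_id!r}")
    ev = db.events_for(patient_id)
    best: tuple[pd.Timestamp, int] | None = None
    channel_sets = {
        "diagnosis": (CodeSystem.ICD10, code_config.outcome_diagnosis),
        "drug": (CodeSystem.ATC_EPHMRA, code_config.outcome_drug),
        "surgery": (CodeSystem.JP_PROCEDURE, code_config.outcome_surgery),
    }
    for rank, channel in enumerate(CHANNELS):
        system, cs = channel_sets[channel]
        sub = ev[ev["system"] == system.value]
        if len(sub):
            sub = sub[cs.mask(sub["code"])]
        if len(sub):
            d = sub["date"].min()
            if best is None or (d, rank) < best:
                best = (d, rank)
    if best is None:
        return None
    return OutcomeHit(patient_id, best[0].date(), CHANNELS[best[1]])


@dataclass
class _CohortArrays:
    """Column cache for vectorized eligibility masks."""

    patient_id: np.ndarray
    sex: np.ndarray
    age: np.ndarray
    entry_mi: np.ndarray
    obs_months: np.ndarray
    duration_to_index: np.ndarray  # -1 for non-cases

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame) -> "_CohortArrays":
        c = cohort.sort_values("patient_id", kind="stable")
        return cls(
            patient_id=c["patient_id"].to_numpy(),
            sex=c["sex"].to_numpy(),
            age=c["age_at_entry"].to_numpy(),
            entry_mi=month_index_series(c["entry_date"]),
            obs_months=c["observation_months"].to_numpy(),
            duration_to_index=c["duration_to_index"].to_numpy(),
        )


def _eligible_mask(arr: _CohortArrays, case_pos: int, params: MatchingParams) -> np.ndarray:
    dur = arr.duration_to_index[case_pos]
    mask = (
        (arr.sex == arr.sex[case_pos])
        & (np.abs(arr.age - arr.age[case_pos]) <= params.age_caliper_years)
        & (np.abs(arr.entry_mi - arr.entry_mi[case_pos]) <= params.entry_caliper_months)
        & (arr.obs_months >= dur)
    )
    # outcome-free at the case's duration: no index, or a strictly later one
    if params.allow_future_cases:
        mask &= (arr.duration_to_index < 0) | (arr.duration_to_index > dur)
    else:
        mask &= arr.duration_to_index < 0
    mask[case_pos] = False
    return mask


def eligible_controls(
    case_id: str, cohort: pd.DataFrame, params: MatchingParams | None = None
) -> list[str]:
    """Patient ids of all risk-set candidates for one case, sorted."""
    params = params or MatchingParams()
    arr = _CohortArrays.from_cohort(cohort)
    pos = np.flatnonzero(arr.patient_id == case_id)
    if not len(pos):
        raise KeyError(f"case {case_id!r} not in cohort")
    if arr.duration_to_index[pos[0]] < 0:
        raise ValueError(f"patient {case_id!r} is not a case")
    mask = _eligible_mask(arr, int(pos[0]), params)
    return list(arr.patient_id[mask])


def sample_matched_sets(
    cohort: pd.DataFrame, params: MatchingParams
) -> tuple[list[MatchedSet], SamplingLog]:
    """Risk-set sampling of up to ``max_controls`` controls per case.

    Cases are processed in ascending index-date order (ties by patient_id);
    candidates are kept sorted by patient_id and drawn without replacement
    within a set via a single seeded stream, so output is deterministic
    given the cohort and the seed, and invariant to input row order.
    """
    arr = _CohortArrays.from_cohort(cohort)
    case_pos = np.flatnonzero(arr.duration_to_index >= 0)
    # ascending case index date (entry month + duration approximates exact
    # date ordering only; sort on true index date instead)
    c = cohort.sort_values("patient_id", kind="stable")
    index_dates = c["index_date"].to_numpy()
    order = sorted(
        case_pos, key=lambda p: (index_dates[p], arr.patient_id[p])
    )
    rng = np.random.default_rng(params.seed)
    sets: list[MatchedSet] = []
    log = SamplingLog(n_cases=len(case_pos), n_sets=0)
    for set_id, pos in enumerate(order):
        mask = _eligible_mask(arr, int(pos), params)
        cand = np.flatnonzero(mask)
        log.pool_sizes[str(arr.patient_id[pos])] = int(len(cand))
        if len(cand) == 0:
            log.dropped_cases.append(str(arr.patient_id[pos]))
            continue
        k = min(params.max_controls, len(cand))
        chosen = rng.choice(len(cand), size=k, replace=False)
        controls = tuple(sorted(arr.patient_id[cand[np.sort(chosen)]]))
        sets.append(
            MatchedSet(
                set_id=len(sets),
                case_id=str(arr.patient_id[pos]),
                control_ids=controls,
                index_date=pd.Timestamp(index_dates[pos]).date(),
                case_duration_months=int(arr.duration_to_index[pos]),
            )
        )
    log.n_sets = len(sets)
    return sets, log


def sets_to_frame(sets: list[MatchedSet]) -> pd.DataFrame:
    """Long format: one row per set member (role 'case' or 'control')."""
    rows = []
    for s in sets:
        rows.append((s.set_id, "case", s.case_id, s.index_date, s.case_duration_months))
        for pid in s.control_ids:
            rows.append((s.set_id, "control", pid, s.index_date, s.case_duration_months))
    return pd.DataFrame(
        rows,
        columns=["set_id", "role", "patient_id", "index_date", "case_duration_months"],
    ).astype({"index_date": "datetime64[ns]"})
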