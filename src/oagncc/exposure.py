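"""Statin exposure windows, Q1/Q2 thresholds, and baseline covariates.

Exposure is the count of statin prescriptions in the half-open window
``[index_date - window_months, index_date)``.  The Q1/Q2 cutoffs are the
25th and 50th percentiles (nearest-rank) of the counts pooled over all
selected cases and controls with at least one in-window prescription; a
member is "Q1 exposed" when their total count reaches Q1 and "Q2 exposed"
when it reaches Q2.  Per-substance exposure applies the same cutoffs to the
substance-specific counts (a member may qualify for several substances).

Baseline covariates are assessed in the six months before cohort entry:
a diagnosis covariate requires matching codes on at least two distinct
dates in ``[entry - 6 months, entry)``; a co-medication covariate requires
at least one prescription there; the infectious/inflammatory composite is
positive when any of its sub-groups satisfies the diagnosis rule.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._dates import add_months, add_months_series
from .claims import ClaimsDatabase, CodeSystem, StatinCatalog
from .config import COVARIATE_ORDER, CodeConfig

SUBSTANCES = StatinCatalog.SUBSTANCES


@dataclass(frozen=True)
class ExposureThresholds:
    model_id: str
    q1: int
    q2: int
    n_contributing: int

    def __post_init__(self) -> None:
        if not 1 <= self.q1 <= self.q2:
            raise ValueError("thresholds must satisfy 1 <= q1 <= q2")


def nearest_rank(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: value at position ceil(p*n) of the sorted list."""
    n = len(sorted_values)
    if n == 0:
        raise ValueError("empty list")
    k = max(math.ceil(p * n), 1)
    return sorted_values[k - 1]


def exposure_thresholds(counts, model_id: str) -> ExposureThresholds:
    """Q1/Q2 cutoffs from the pooled positive prescription counts."""
    arr = np.sort(np.asarray(list(counts), dtype=int))
    if len(arr) == 0:
        raise ValueError("no statin users: cannot compute exposure thresholds")
    if arr[0] < 1:
        raise ValueError("threshold counts must be positive (users only)")
    return ExposureThresholds(
        model_id=model_id,
        q1=int(nearest_rank(arr, 0.25)),
        q2=int(nearest_rank(arr, 0.50)),
        n_contributing=len(arr),
    )


def count_statin_prescriptions(
    db: ClaimsDatabase,
    patient_id: str,
    index_date: dt.date,
    window_months: int,
    code_config: CodeConfig,
) -> tuple[int, dict[str, int]]:
    """Total and per-substance statin prescription counts in the window
    ``[index_date - window_months, index_date)``."""
    if window_months not in (12, 24):
        raise ValueError("window_months must be 12 or 24")
    start = add_months(index_date, -window_months)
    per = {}
    for sub in SUBSTANCES:
        code = code_config.statins.code_of(sub)
        ev = db.events_for(patient_id)
        ev = ev[
            (ev["system"] == CodeSystem.ATC_EPHMRA.value)
            & (ev["code"] == code)
            & (ev["date"] >= pd.Timestamp(start))
            & (ev["date"] < pd.Timestamp(index_date))
        ]
        per[sub] = int(len(ev))
    return sum(per.values()), per


def count_statins_bulk(
    db: ClaimsDatabase,
    members: pd.DataFrame,
    window_months: int,
    code_config: CodeConfig,
) -> pd.DataFrame:
    """Vectorized counts for a member frame with columns (set_id,
    patient_id, index_date); returns one row per member with total and
    per-substance counts."""
    code_to_sub = {code_config.statins.code_of(s): s for s in SUBSTANCES}
    rx = db.events[db.events["system"] == CodeSystem.ATC_EPHMRA.value]
    rx = rx[rx["code"].isin(code_to_sub)]
    out = members[["set_id", "patient_id", "index_date"]].copy()
    out["window_start"] = add_months_series(out["index_date"], -window_months).to_numpy()
    merged = out.merge(rx, on="patient_id", how="left")
    in_win = (
        merged["date"].notna()
        & (merged["date"] >= merged["window_start"])
        & (merged["date"] < merged["index_date"])
    )
    merged = merged[in_win]
    merged["substance"] = merged["code"].map(code_to_sub)
    counts = (
        merged.groupby(["set_id", "patient_id", "substance"], observed=True)
        .size()
        .unstack("substance", fill_value=0)
        if len(merged)
        else pd.DataFrame()
    )
    for sub in SUBSTANCES:
        if sub not in counts.columns:
            counts[sub] = 0
    counts = counts[list(SUBSTANCES)] if len(counts) else counts
    result = out.merge(
        counts.reset_index() if len(counts) else pd.DataFrame(
            columns=["set_id", "patient_id", *SUBSTANCES]
        ),
        on=["set_id", "patient_id"],
        how="left",
    )
    for sub in SUBSTANCES:
        result[sub] = result[sub].fillna(0).astype(int)
    result["total_count"] = result[list(SUBSTANCES)].sum(axis=1)
    return result.drop(columns=["window_start"])


@dataclass(frozen=True)
class ExposureRecord:
    patient_id: str
    set_id: int
    total_count: int
    per_substance_counts: dict[str, int]
    exposed_q1: bool
    exposed_q2: bool
    per_substance_exposed_q1: dict[str, bool]
    per_substance_exposed_q2: dict[str, bool]


def classify_exposure(
    patient_id: str,
    set_id: int,
    total_count: int,
    per_substance_counts: dict[str, int],
    thresholds: ExposureThresholds,
) -> ExposureRecord:
    if total_count != sum(per_substance_counts.values()):
        raise ValueError("total_count must equal the sum of per-substance counts")
    return ExposureRecord(
        patient_id=patient_id,
        set_id=set_id,
        total_count=total_count,
        per_substance_counts=dict(per_substance_counts),
        exposed_q1=total_count >= thresholds.q1,
        exposed_q2=total_count >= thresholds.q2,
        per_substance_exposed_q1={
            s: per_substance_counts.get(s, 0) >= thresholds.q1 for s in SUBSTANCES
        },
        per_substance_exposed_q2={
            s: per_substance_counts.get(s, 0) >= thresholds.q2 for s in SUBSTANCES
        },
    )


def classify_exposure_frame(
    counts: pd.DataFrame, thresholds: ExposureThresholds
) -> pd.DataFrame:
    """Add exposure flags to a bulk count frame (see count_statins_bulk)."""
    out = counts.copy()
    out["exposed_q1"] = out["total_count"] >= thresholds.q1
    out["exposed_q2"] = out["total_count"] >= thresholds.q2
    for sub in SUBSTANCES:
        out[f"{sub}_q1"] = out[sub] >= thresholds.q1
        out[f"{sub}_q2"] = out[sub] >= thresholds.q2
    return out


def assess_covariates(
    db: ClaimsDatabase,
    patient_id: str,
    entry_date: dt.date,
    code_config: CodeConfig,
) -> dict[str, bool]:
    """Fourteen baseline covariate flags for one patient (fixed order)."""
    start = pd.Timestamp(add_months(entry_date, -6))
    end = pd.Timestamp(entry_date)
    ev = db.events_for(patient_id)
    ev = ev[(ev["date"] >= start) & (ev["date"] < end)]
    flags: dict[str, bool] = {}
    for cov in code_config.covariates:
        hit = False
        for cs in cov.code_sets:
            sub = ev[ev["system"] == cs.system.value]
            if len(sub):
                sub = sub[cs.mask(sub["code"])]
            if not len(sub):
                continue
            if cov.kind == "medication":
                hit = True
            else:  # diagnosis rule: two or more distinct service dates
                hit = sub["date"].nunique() >= 2
            if hit:
                break
        flags[cov.name] = hit
    return flags


def covariate_table(
    db: ClaimsDatabase, patients: pd.DataFrame, code_config: CodeConfig
) -> pd.DataFrame:
    """Vectorized covariate flags for a frame with (patient_id, entry_date).

    One row per input row, columns = the 14 covariate names in order.
    """
    base = patients[["patient_id", "entry_date"]].drop_duplicates("patient_id")
    wstart = add_months_series(base["entry_date"], -6)
    spans = pd.DataFrame(
        {
            "patient_id": base["patient_id"].to_numpy(),
            "_wstart": wstart.to_numpy(),
            "_entry": base["entry_date"].to_numpy(),
        }
    )
    ev = db.events.merge(spans, on="patient_id", how="inner")
    ev = ev[(ev["date"] >= ev["_wstart"]) & (ev["date"] < ev["_entry"])]
    out = pd.DataFrame({"patient_id": base["patient_id"].to_numpy()})
    for cov in code_config.covariates:
        positive: set[str] = set()
        for cs in cov.code_sets:
            sub = ev[ev["system"] == cs.system.value]
            if len(sub):
                sub = sub[cs.mask(sub["code"])]
            if not len(sub):
                continue
            if cov.kind == "medication":
                positive |= set(sub["patient_id"])
            else:
                nun = sub.groupby("patient_id")["date"].nunique()
                positive |= set(nun[nun >= 2].index)
        out[cov.name] = out["patient_id"].isin(positive)
    for name in COVARIATE_ORDER:
        if name not in out.columns:
            out[name] = False
    return out[["patient_id", *COVARIATE_ORDER]]
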