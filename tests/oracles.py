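"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately written with plain per-patient loops and their own date
arithmetic, sharing no window/matching logic with the package.  (Events are
pulled out of the frame in one pass for speed; all decisions are per-patient
Python.)
"""

import calendar
import datetime as dt
from collections import defaultdict

STEP_ORDER = [
    "dyslipidemia",
    "run_in",
    "confirmation",
    "age",
    "prior_outcome",
    "prior_statin",
    "observation",
]

STATIN_CODES = {"C10A11", "C10A12", "C10A13", "C10A14", "C10A15", "C10A16"}
OUTCOME_DIAG = {"H401", "H406", "H409"}


def _add_months(d: dt.date, n: int) -> dt.date:
    mi = d.year * 12 + (d.month - 1) + n
    y, m = divmod(mi, 12)
    return dt.date(y, m + 1, min(d.day, calendar.monthrange(y, m + 1)[1]))


def _whole_months(a: dt.date, b: dt.date) -> int:
    m = (b.year - a.year) * 12 + (b.month - a.month)
    if b.day < a.day:
        m -= 1
    return m


def _events_by_patient(db):
    by_pid = defaultdict(list)
    for pid, date, system, code in zip(
        db.events["patient_id"], db.events["date"], db.events["system"], db.events["code"]
    ):
        by_pid[pid].append((date.date(), system, code))
    return by_pid


def _first_outcome(events):
    """(date, channel rank) of the earliest composite-outcome event, else None."""
    best = None
    for d, system, code in events:
        if system == "ICD10" and code in OUTCOME_DIAG:
            cand = (d, 0)
        elif system == "ATC_EPHMRA" and code.startswith("S1E2"):
            cand = (d, 1)
        elif system == "JP_PROCEDURE" and code == "K268":
            cand = (d, 2)
        else:
            continue
        if best is None or cand < best:
            best = cand
    return best


def brute_force_eligibility(db, min_followup: int):
    """Per-patient eligibility decisions.

    Returns {patient_id: (exclusion step name or None, record dict)}.
    """
    by_pid = _events_by_patient(db)
    out = {}
    for pid, sex, birth, estart in zip(
        db.patients["patient_id"],
        db.patients["sex"],
        db.patients["birth_ym"],
        db.patients["enroll_start"],
    ):
        events = by_pid.get(pid, [])
        dysl_dates = sorted(
            d for d, system, code in events if system == "ICD10" and code.startswith("E78")
        )
        if not dysl_dates:
            out[pid] = ("dyslipidemia", None)
            continue
        entry, last = dysl_dates[0], dysl_dates[-1]
        if _whole_months(estart.date(), entry) < 6:
            out[pid] = ("run_in", None)
            continue
        confirm_end = _add_months(entry, 6)
        if not any(entry < d <= confirm_end for d in dysl_dates):
            out[pid] = ("confirmation", None)
            continue
        age = _whole_months(birth.date(), entry) // 12
        if age < 20:
            out[pid] = ("age", None)
            continue
        hit = _first_outcome(events)
        if hit is not None and hit[0] <= entry:
            out[pid] = ("prior_outcome", None)
            continue
        if any(
            d < entry
            for d, system, code in events
            if system == "ATC_EPHMRA" and code in STATIN_CODES
        ):
            out[pid] = ("prior_statin", None)
            continue
        is_case = hit is not None and hit[0] <= last
        obs_end = hit[0] if is_case else last
        obs_months = _whole_months(entry, obs_end)
        if obs_months < min_followup:
            out[pid] = ("observation", None)
            continue
        out[pid] = (
            None,
            {
                "entry": entry,
                "age": age,
                "sex": sex,
                "obs_months": obs_months,
                "is_case": is_case,
                "index_date": hit[0] if is_case else None,
                "duration": _whole_months(entry, hit[0]) if is_case else None,
            },
        )
    return out


def verify_matched_set(case_rec, control_recs, params_age=5, params_entry=3):
    """Re-check every sampled control against all five eligibility
    predicates; returns list of violation strings."""
    violations = []
    dur = case_rec["duration"]
    for pid, rec in control_recs.items():
        if rec["sex"] != case_rec["sex"]:
            violations.append(f"{pid}: sex")
        if abs(rec["age"] - case_rec["age"]) > params_age:
            violations.append(f"{pid}: age")
        e1 = rec["entry"].year * 12 + rec["entry"].month
        e2 = case_rec["entry"].year * 12 + case_rec["entry"].month
        if abs(e1 - e2) > params_entry:
            violations.append(f"{pid}: entry month")
        if rec["obs_months"] < dur:
            violations.append(f"{pid}: observation shorter than case duration")
        if rec["is_case"] and rec["duration"] <= dur:
            violations.append(f"{pid}: not outcome-free at case duration")
    return violations
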