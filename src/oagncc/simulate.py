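"""Synthetic claims generator with known ground truth.

Emulates the structure the nested case–control analysis assumes: a
working-age dyslipidemia cohort with dated ICD-10 diagnoses, EphMRA-ATC
prescriptions and a procedure code, time-varying statin prescribing, and an
open-angle glaucoma outcome process with a configurable true exposure
effect.

The simulation runs on a discrete monthly grid (claims are visit and
dispensing events; all analysis windows are month-denominated).  Events are
dated on the first day of their month.  Each patient:

* enrolls at a uniform calendar month, is diagnosed with dyslipidemia
  (first E78 code) after a run-in of ``run_in_months`` (plus a small random
  extra), and — with probability ``confirm_visit_prob`` — keeps visiting
  monthly (further E78 codes) until dropout or the calendar end;
* carries independent comorbidity flags; a true comorbidity emits two codes
  on distinct months of the six-month pre-diagnosis window (the analysis
  requires at least two occurrences), and single-occurrence noise codes are
  sprinkled on negative patients to exercise that rule;
* may initiate a statin within ``initiation_window_months`` of diagnosis
  (treatment decisions cluster at diagnosis); therapy is absorbing, and a
  prescription claim is emitted each month on therapy with probability
  ``refill_monthly_prob``;
* has a discrete-time proportional-hazards outcome,
  ``h(t) = baseline * exp(log_or["statin"] * X(t) + sum_c log_or[c] * C_c)``,
  where ``X(t)`` indicates being on statin therapy in month ``t``; at the
  first outcome month exactly one outcome event is emitted, drawn from the
  three composite-outcome channels (diagnosis H401 / anti-glaucoma drug
  S1E2 / surgery K268).

A small fraction of patients get a pre-diagnosis outcome event or a
pre-diagnosis statin prescription so that every cohort exclusion step is
exercised.

Randomness is a single seeded stream with per-patient substreams derived
from ``(seed, patient index)``, so growing ``n_patients`` leaves earlier
patients unchanged.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._dates import month_index
from .claims import ClaimsDatabase, CodeSystem, ConfigError, StatinCatalog
from .config import COVARIATE_ORDER, CodeConfig, load_code_config

SUBSTANCES = StatinCatalog.SUBSTANCES

OUTCOME_CHANNELS = ("diagnosis", "drug", "surgery")


def default_comorbidity_prevalences() -> dict[str, float]:
    """Roughly the control-arm comorbidity frequencies of a working-age
    dyslipidemia population, floored at 1% for the very rare conditions so
    that adjusted regressions at simulation scale stay identified."""
    return {
        "diabetes_mellitus": 0.09,
        "hypertension": 0.22,
        "hypotension": 0.01,
        "hyperuricemia_gout": 0.055,
        "arrhythmia_heart_failure": 0.035,
        "ischemic_heart_disease": 0.026,
        "cerebrovascular_disease": 0.024,
        "transient_ischemic_attack": 0.01,
        "migraine": 0.013,
        "obstructive_sleep_apnea": 0.012,
        "myopia": 0.015,
        "infectious_inflammatory": 0.024,
        "beta_blocker": 0.033,
        "steroid": 0.10,
    }


def default_log_or() -> dict[str, float]:
    """Null statin effect; modest true effects for the covariates that the
    literature flags as risk factors (diabetes, myopia, steroids)."""
    lor = {name: 0.0 for name in COVARIATE_ORDER}
    lor["statin"] = 0.0
    lor["diabetes_mellitus"] = np.log(1.3)
    lor["hypertension"] = np.log(1.1)
    lor["arrhythmia_heart_failure"] = np.log(1.1)
    lor["obstructive_sleep_apnea"] = np.log(1.1)
    lor["myopia"] = np.log(2.2)
    lor["steroid"] = np.log(1.35)
    return lor


@dataclass
class SimulationConfig:
    n_patients: int = 5000
    seed: int = 0
    calendar_start: dt.date = dt.date(2005, 1, 1)
    calendar_end: dt.date = dt.date(2020, 1, 1)
    sex_male_prob: float = 0.60
    age_mean: float = 51.0
    age_sd: float = 8.0
    age_min: float = 20.0
    age_max: float = 74.0
    run_in_months: int = 6
    extra_run_in_max_months: int = 3
    confirm_visit_prob: float = 0.85
    statin_initiation_monthly_prob: float = 0.20
    initiation_window_months: int = 3
    refill_monthly_prob: float = 0.97
    statin_mix: tuple[float, ...] = (0.30, 0.27, 0.16, 0.12, 0.08, 0.07)
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=default_comorbidity_prevalences
    )
    comorbidity_noise_prob: float = 0.03
    baseline_oag_monthly_hazard: float = 0.002
    log_or: dict[str, float] = field(default_factory=default_log_or)
    outcome_channel_probs: tuple[float, float, float] = (0.75, 0.24, 0.01)
    dropout_monthly_prob: float = 0.02
    pre_entry_statin_prob: float = 0.01
    prevalent_outcome_prob: float = 0.015

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        probs = {
            "sex_male_prob": self.sex_male_prob,
            "confirm_visit_prob": self.confirm_visit_prob,
            "statin_initiation_monthly_prob": self.statin_initiation_monthly_prob,
            "refill_monthly_prob": self.refill_monthly_prob,
            "comorbidity_noise_prob": self.comorbidity_noise_prob,
            "dropout_monthly_prob": self.dropout_monthly_prob,
            "pre_entry_statin_prob": self.pre_entry_statin_prob,
            "prevalent_outcome_prob": self.prevalent_outcome_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        for name, p in self.comorbidity_prevalences.items():
            if name not in COVARIATE_ORDER:
                raise ConfigError(f"unknown comorbidity {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"prevalence of {name!r} must be in [0,1]")
        if set(self.comorbidity_prevalences) != set(COVARIATE_ORDER):
            raise ConfigError("comorbidity_prevalences must cover all 14 covariates")
        for key in self.log_or:
            if key != "statin" and key not in COVARIATE_ORDER:
                raise ConfigError(f"unknown log_or term {key!r}")
        if len(self.statin_mix) != len(SUBSTANCES):
            raise ConfigError("statin_mix must have six entries")
        if abs(sum(self.statin_mix) - 1.0) > 1e-9 or min(self.statin_mix) < 0:
            raise ConfigError("statin_mix must be a probability vector summing to 1")
        if abs(sum(self.outcome_channel_probs) - 1.0) > 1e-9 or min(self.outcome_channel_probs) < 0:
            raise ConfigError("outcome_channel_probs must sum to 1")
        if self.baseline_oag_monthly_hazard < 0:
            raise ConfigError("baseline hazard must be >= 0")
        if self.dropout_monthly_prob <= 0:
            raise ConfigError("dropout_monthly_prob must be > 0")
        if self.calendar_start >= self.calendar_end:
            raise ConfigError("calendar_start must precede calendar_end")
        if self.initiation_window_months < 1:
            raise ConfigError("initiation_window_months must be >= 1")


#: GroundTruth frame columns (one row per patient; ``cov_*`` flags follow)
TRUTH_BASE_COLUMNS = [
    "patient_id",
    "sex",
    "age_at_entry",
    "onset_date",
    "enroll_start",
    "enroll_end",
    "continuer",
    "statin_init_date",
    "substance",
    "outcome_date",
    "outcome_channel",
    "prevalent_outcome",
    "pre_entry_statin",
    "months_enrolled_after_onset",
]


def _representative_codes(code_config: CodeConfig) -> dict[str, list[tuple[str, str]]]:
    """Per covariate: list of (system, emittable code) choices.

    Range entries contribute their lower endpoint; composites one code per
    sub-group.
    """
    reps: dict[str, list[tuple[str, str]]] = {}
    for cov in code_config.covariates:
        choices: list[tuple[str, str]] = []
        for cs in cov.code_sets:
            entry = cs.entries[0]
            code = entry.split("-")[0] if "-" in entry else entry
            choices.append((cs.system.value, code.upper().replace(".", "")))
        reps[cov.name] = choices
    return reps


def simulate(
    config: SimulationConfig, code_config: CodeConfig | None = None
) -> tuple[ClaimsDatabase, pd.DataFrame]:
    """Generate a claims database and its per-patient ground truth.

    Deterministic given ``config`` (including its seed).  Returns the
    database and a GroundTruth DataFrame with one row per patient carrying
    the latent simulation record: true covariate flags (``cov_*`` columns),
    statin initiation date and substance, true outcome month and channel,
    and enrollment bookkeeping.  The per-month active-exposure indicator is
    implicit: exposure is on from ``statin_init_date`` (absorbing); see
    :func:`active_exposure_months`.
    """
    cc = code_config if code_config is not None else load_code_config()
    dysl_code = "E78"
    outcome_codes = {
        "diagnosis": (CodeSystem.ICD10.value, cc.outcome_diagnosis.entries[0]),
        "drug": (CodeSystem.ATC_EPHMRA.value, cc.outcome_drug.entries[0]),
        "surgery": (CodeSystem.JP_PROCEDURE.value, cc.outcome_surgery.entries[0]),
    }
    statin_codes = [cc.statins.code_of(s) for s in SUBSTANCES]
    cov_reps = _representative_codes(cc)
    cov_names = list(COVARIATE_ORDER)
    prevalences = np.array([config.comorbidity_prevalences[c] for c in cov_names])
    lor_cov = np.array([config.log_or.get(c, 0.0) for c in cov_names])
    lor_statin = config.log_or.get("statin", 0.0)
    mix = np.asarray(config.statin_mix)
    chan_probs = np.asarray(config.outcome_channel_probs)

    start_mi = month_index(config.calendar_start)
    end_mi = month_index(config.calendar_end)
    horizon = end_mi - start_mi
    pre_span = config.run_in_months + config.extra_run_in_max_months
    onset_slots = max(horizon - pre_span - 1, 1)

    n = config.n_patients
    pid_width = max(6, len(str(max(n - 1, 0))))
    patient_ids = np.array([f"P{i:0{pid_width}d}" for i in range(n)], dtype=object)

    # patient-level outputs
    sex = np.empty(n, dtype=object)
    age = np.zeros(n, dtype=int)
    birth_mi = np.zeros(n, dtype=int)
    e0_mi = np.zeros(n, dtype=int)
    onset_mi = np.zeros(n, dtype=int)
    end_enroll_mi = np.zeros(n, dtype=int)
    continuer = np.zeros(n, dtype=bool)
    flags = np.zeros((n, len(cov_names)), dtype=bool)
    init_mi = np.full(n, -1, dtype=int)  # -1: never initiated
    substance_idx = np.full(n, -1, dtype=int)
    outcome_mi = np.full(n, -1, dtype=int)
    channel_idx = np.full(n, -1, dtype=int)
    prevalent = np.zeros(n, dtype=bool)
    pre_statin = np.zeros(n, dtype=bool)

    # event accumulator: per chunk a months array plus constant (pid, system,
    # code) metadata, expanded once at the end
    ev_meta: list[tuple[str, str, str, int]] = []
    ev_mi: list[np.ndarray] = []

    def emit(i: int, months: np.ndarray, system: str, code: str) -> None:
        k = len(months)
        if k == 0:
            return
        ev_meta.append((patient_ids[i], system, code, k))
        ev_mi.append(np.asarray(months, dtype=int))

    for i in range(n):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(i,))
        )
        sex[i] = "M" if rng.random() < config.sex_male_prob else "F"
        age_f = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                              config.age_min, config.age_max))
        age[i] = int(age_f)
        extra_birth = int(rng.integers(0, 12))
        e0 = start_mi + int(rng.integers(0, onset_slots))
        extra_run = int(rng.integers(0, config.extra_run_in_max_months + 1))
        onset = e0 + config.run_in_months + extra_run
        birth_mi[i] = onset - (age[i] * 12 + extra_birth)
        e0_mi[i] = e0
        onset_mi[i] = onset
        # enrollment after diagnosis: independent monthly dropout, calendar-capped
        dur = int(rng.geometric(config.dropout_monthly_prob))
        end_e = min(onset + dur, end_mi)
        end_enroll_mi[i] = end_e
        months_after = end_e - onset

        continuer[i] = rng.random() < config.confirm_visit_prob
        if continuer[i]:
            emit(i, np.arange(onset, end_e + 1), CodeSystem.ICD10.value, dysl_code)
        else:
            emit(i, np.array([onset]), CodeSystem.ICD10.value, dysl_code)

        # comorbidities: two distinct pre-onset months if truly present,
        # a single-occurrence noise code otherwise
        f = rng.random(len(cov_names)) < prevalences
        flags[i] = f
        noise = rng.random(len(cov_names)) < config.comorbidity_noise_prob
        for j, name in enumerate(cov_names):
            choices = cov_reps[name]
            system, code = choices[int(rng.integers(0, len(choices)))]
            is_med = system == CodeSystem.ATC_EPHMRA.value
            if f[j]:
                if is_med:
                    offs = rng.integers(1, 7, size=1)
                else:
                    offs = rng.choice(6, size=2, replace=False) + 1
                emit(i, onset - np.sort(offs)[::-1], system, code)
            elif noise[j] and not is_med:
                emit(i, onset - np.array([int(rng.integers(1, 7))]), system, code)

        if rng.random() < config.pre_entry_statin_prob:
            pre_statin[i] = True
            emit(
                i,
                onset - np.array([int(rng.integers(1, 7))]),
                CodeSystem.ATC_EPHMRA.value,
                statin_codes[int(rng.choice(len(SUBSTANCES), p=mix))],
            )

        # statin initiation near diagnosis; therapy absorbing thereafter
        u_init = rng.random(config.initiation_window_months)
        hits = np.flatnonzero(u_init < config.statin_initiation_monthly_prob)
        s_idx = int(rng.choice(len(SUBSTANCES), p=mix))
        if len(hits):
            t0 = int(hits[0])
            if t0 <= months_after:
                init_mi[i] = onset + t0
                substance_idx[i] = s_idx
                n_on = months_after - t0 + 1
                refill = rng.random(n_on) < config.refill_monthly_prob
                refill[0] = True  # the initiation fill itself
                emit(
                    i,
                    onset + t0 + np.flatnonzero(refill),
                    CodeSystem.ATC_EPHMRA.value,
                    statin_codes[s_idx],
                )

        channel = int(rng.choice(3, p=chan_probs))
        if rng.random() < config.prevalent_outcome_prob:
            prevalent[i] = True
            m = onset - int(rng.integers(1, 7))
            outcome_mi[i] = m
            channel_idx[i] = channel
            system, code = outcome_codes[OUTCOME_CHANNELS[channel]]
            emit(i, np.array([m]), system, code)
        elif config.baseline_oag_monthly_hazard > 0:
            # two-segment geometric sampling of the discrete-time hazard,
            # months t = 1..months_after (t relative to diagnosis)
            h0 = min(
                config.baseline_oag_monthly_hazard * float(np.exp(flags[i] @ lor_cov)),
                0.999,
            )
            h1 = min(h0 * float(np.exp(lor_statin)), 0.999)
            first_exposed = init_mi[i] - onset if init_mi[i] >= 0 else np.inf
            n_unexposed = int(max(first_exposed - 1, 0)) if np.isfinite(first_exposed) else None
            g0 = int(rng.geometric(h0)) if h0 > 0 else None
            t_out: int | None = None
            if n_unexposed is None:  # never exposed
                t_out = g0
            elif g0 is not None and g0 <= n_unexposed:
                t_out = g0
            else:
                g1 = int(rng.geometric(h1)) if h1 > 0 else None
                if g1 is not None:
                    t_out = n_unexposed + g1
            if t_out is not None and t_out <= months_after:
                m = onset + t_out
                outcome_mi[i] = m
                channel_idx[i] = channel
                system, code = outcome_codes[OUTCOME_CHANNELS[channel]]
                emit(i, np.array([m]), system, code)

    # ---- assemble frames -------------------------------------------------

    def mi_to_ts(mi: np.ndarray) -> pd.Series:
        mi = np.asarray(mi, dtype=int)
        return pd.to_datetime(
            {"year": mi // 12 + 1900, "month": mi % 12 + 1, "day": np.ones(len(mi), dtype=int)}
        )

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": sex,
            "birth_ym": mi_to_ts(birth_mi),
            "enroll_start": mi_to_ts(e0_mi),
            "enroll_end": mi_to_ts(end_enroll_mi),
        }
    )
    if ev_meta:
        lengths = np.array([m[3] for m in ev_meta])
        events = pd.DataFrame(
            {
                "patient_id": np.repeat(
                    np.array([m[0] for m in ev_meta], dtype=object), lengths
                ),
                "date": mi_to_ts(np.concatenate(ev_mi)),
                "system": np.repeat(
                    np.array([m[1] for m in ev_meta], dtype=object), lengths
                ),
                "code": np.repeat(
                    np.array([m[2] for m in ev_meta], dtype=object), lengths
                ),
            }
        )
    else:
        events = pd.DataFrame(columns=["patient_id", "date", "system", "code"])
    db = ClaimsDatabase(patients, events, validate=False)

    def opt_dates(mi: np.ndarray) -> pd.Series:
        out = mi_to_ts(np.where(mi < 0, 0, mi))
        return out.where(pd.Series(mi >= 0), pd.NaT)

    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": sex,
            "age_at_entry": age,
            "onset_date": mi_to_ts(onset_mi),
            "enroll_start": mi_to_ts(e0_mi),
            "enroll_end": mi_to_ts(end_enroll_mi),
            "continuer": continuer,
            "statin_init_date": opt_dates(init_mi),
            "substance": [
                SUBSTANCES[k] if k >= 0 else None for k in substance_idx
            ],
            "outcome_date": opt_dates(outcome_mi),
            "outcome_channel": [
                OUTCOME_CHANNELS[k] if k >= 0 else None for k in channel_idx
            ],
            "prevalent_outcome": prevalent,
            "pre_entry_statin": pre_statin,
            "months_enrolled_after_onset": end_enroll_mi - onset_mi,
        }
    )
    for j, name in enumerate(cov_names):
        truth[f"cov_{name}"] = flags[:, j]
    return db, truth


def active_exposure_months(truth_row: pd.Series) -> tuple[int, int] | None:
    """Half-open month-index span [start, end) of active statin exposure for
    one GroundTruth row, or None if the patient never initiated."""
    if pd.isna(truth_row["statin_init_date"]):
        return None
    start = month_index(truth_row["statin_init_date"].date())
    end = month_index(truth_row["enroll_end"].date()) + 1
    return start, end


def write_ground_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    for col in ("onset_date", "enroll_start", "enroll_end", "statin_init_date", "outcome_date"):
        out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
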