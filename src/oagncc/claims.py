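"""Claims-shaped data model: patients, dated coded events, code-set matching, CSV I/O.

The universal input of the pipeline is a :class:`ClaimsDatabase` — a patient
table (id, sex, birth year-month, enrollment span) plus per-patient,
date-sorted coded events in one of three systems: ICD-10 diagnoses,
EphMRA-ATC prescriptions, and Japanese procedure codes.

Codes are normalized to dotless uppercase ("H40.1" -> "H401").  A
:class:`CodeSet` entry is either an exact/prefix code ("E78" matches "E78"
and any subcode "E780") or an inclusive range ("I20-I25", compared
lexicographically at the range's prefix length).
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class CodeSystem(str, enum.Enum):
    ICD10 = "ICD10"
    ATC_EPHMRA = "ATC_EPHMRA"
    JP_PROCEDURE = "JP_PROCEDURE"


class ClaimsError(ValueError):
    """Validation failure in claims-shaped inputs."""


class ConfigError(ValueError):
    """Malformed code-set or simulation configuration."""


DATE_MIN = dt.date(1900, 1, 1)
DATE_MAX = dt.date(2100, 1, 1)  # exclusive


def normalize_code(code: str) -> str:
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    sex: str  # "M" | "F"
    birth_ym: dt.date  # first day of birth month
    enroll_start: dt.date
    enroll_end: dt.date

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ClaimsError(f"patient {self.patient_id}: sex must be M or F")
        if self.enroll_start > self.enroll_end:
            raise ClaimsError(
                f"patient {self.patient_id}: enroll_start after enroll_end"
            )
        if self.birth_ym > self.enroll_start:
            raise ClaimsError(
                f"patient {self.patient_id}: birth_ym after enroll_start"
            )


@dataclass(frozen=True)
class ClaimEvent:
    patient_id: str
    date: dt.date
    system: CodeSystem
    code: str

    def __post_init__(self) -> None:
        if not self.code:
            raise ClaimsError(f"patient {self.patient_id}: empty event code")
        if not (DATE_MIN <= self.date < DATE_MAX):
            raise ClaimsError(
                f"patient {self.patient_id}: event date {self.date} out of range"
            )


@dataclass(frozen=True)
class CodeSet:
    """Named set of code patterns within one code system.

    Entries are exact/prefix codes or inclusive ranges "A-B" whose endpoints
    share the same length.
    """

    name: str
    system: CodeSystem
    entries: tuple[str, ...]

    _prefixes: tuple[str, ...] = field(init=False, repr=False, compare=False)
    _ranges: tuple[tuple[str, str], ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        prefixes: list[str] = []
        ranges: list[tuple[str, str]] = []
        for raw in self.entries:
            entry = normalize_code(raw)
            if "-" in entry:
                parts = entry.split("-")
                if len(parts) != 2 or not all(parts):
                    raise ConfigError(f"code set {self.name!r}: malformed range {raw!r}")
                lo, hi = parts
                if len(lo) != len(hi):
                    raise ConfigError(
                        f"code set {self.name!r}: range endpoints of {raw!r} "
                        "must share prefix length"
                    )
                if lo > hi:
                    raise ConfigError(f"code set {self.name!r}: empty range {raw!r}")
                ranges.append((lo, hi))
            elif entry:
                prefixes.append(entry)
            else:
                raise ConfigError(f"code set {self.name!r}: empty entry")
        object.__setattr__(self, "_prefixes", tuple(prefixes))
        object.__setattr__(self, "_ranges", tuple(ranges))

    def matches(self, code: str) -> bool:
        return match_code(code, self)

    def mask(self, codes: pd.Series) -> np.ndarray:
        """Vectorized membership over a Series of normalized codes."""
        out = np.zeros(len(codes), dtype=bool)
        for p in self._prefixes:
            out |= codes.str.startswith(p).to_numpy()
        for lo, hi in self._ranges:
            trunc = codes.str.slice(0, len(lo))
            out |= ((trunc >= lo) & (trunc <= hi)).to_numpy()
        return out


def match_code(code: str, code_set: CodeSet) -> bool:
    """True iff ``code`` equals/extends a prefix entry or falls inside a range.

    ``code`` is expected normalized (uppercase, dotless); pure and
    deterministic.
    """
    for p in code_set._prefixes:
        if code.startswith(p):
            return True
    for lo, hi in code_set._ranges:
        trunc = code[: len(lo)]
        if lo <= trunc <= hi:
            return True
    return False


@dataclass(frozen=True)
class StatinCatalog:
    """Maps the six statin substances to prescription codes (synthetic dialect)."""

    codes: dict[str, str]  # substance -> ATC_EPHMRA code

    SUBSTANCES = (
        "rosuvastatin",
        "atorvastatin",
        "pitavastatin",
        "pravastatin",
        "simvastatin",
        "fluvastatin",
    )

    def __post_init__(self) -> None:
        if set(self.codes) != set(self.SUBSTANCES):
            raise ConfigError(
                "statin catalog must map exactly the six substances "
                f"{self.SUBSTANCES}, got {sorted(self.codes)}"
            )
        norm = {s: normalize_code(c) for s, c in self.codes.items()}
        if len(set(norm.values())) != len(norm):
            raise ConfigError("statin catalog codes must be disjoint")
        object.__setattr__(self, "codes", norm)

    def substances(self) -> tuple[str, ...]:
        return self.SUBSTANCES

    def code_of(self, substance: str) -> str:
        return self.codes[substance]

    def substance_of(self, code: str) -> str | None:
        for s, c in self.codes.items():
            if code == c:
                return s
        return None

    def as_code_set(self) -> CodeSet:
        return CodeSet(
            "statins", CodeSystem.ATC_EPHMRA, tuple(self.codes[s] for s in self.SUBSTANCES)
        )


PATIENT_COLUMNS = ["patient_id", "sex", "birth_ym", "enroll_start", "enroll_end"]
EVENT_COLUMNS = ["patient_id", "date", "system", "code"]


class ClaimsDatabase:
    """Patient table + per-patient date-sorted claim events.

    Internally two pandas DataFrames; ``patients`` indexed by patient_id,
    ``events`` sorted by (patient_id, date) with a stable sort so same-day
    event order is preserved from input.
    """

    def __init__(self, patients: pd.DataFrame, events: pd.DataFrame, *, validate: bool = True):
        patients = patients.reset_index(drop=True).copy()
        events = events.reset_index(drop=True).copy()
        for col in ("birth_ym", "enroll_start", "enroll_end"):
            patients[col] = pd.to_datetime(patients[col])
        if len(events):
            events["date"] = pd.to_datetime(events["date"])
            if validate:  # trusted callers (the generator) emit normalized codes
                events["code"] = events["code"].map(normalize_code)
        else:
            events = pd.DataFrame(
                {
                    "patient_id": pd.Series([], dtype=str),
                    "date": pd.Series([], dtype="datetime64[ns]"),
                    "system": pd.Series([], dtype=str),
                    "code": pd.Series([], dtype=str),
                }
            )
        if validate:
            self._validate(patients, events)
        events = events.sort_values(["patient_id", "date"], kind="stable").reset_index(
            drop=True
        )
        self.patients = patients
        self.events = events
        self._event_slices: dict[str, slice] | None = None

    @staticmethod
    def _validate(patients: pd.DataFrame, events: pd.DataFrame) -> None:
        if patients["patient_id"].duplicated().any():
            dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].iloc[0]
            raise ClaimsError(f"duplicate patient_id {dup!r}")
        bad_sex = ~patients["sex"].isin(["M", "F"])
        if bad_sex.any():
            raise ClaimsError(f"invalid sex at patient row {int(np.argmax(bad_sex.to_numpy()))}")
        if (patients["enroll_start"] > patients["enroll_end"]).any():
            raise ClaimsError("enroll_start after enroll_end")
        if (patients["birth_ym"] > patients["enroll_start"]).any():
            raise ClaimsError("birth_ym after enroll_start")
        if len(events):
            known = set(patients["patient_id"])
            missing = ~events["patient_id"].isin(known)
            if missing.any():
                row = int(np.argmax(missing.to_numpy()))
                raise ClaimsError(
                    f"event row {row} references unknown patient "
                    f"{events['patient_id'].iloc[row]!r}"
                )
            bad_sys = ~events["system"].isin([s.value for s in CodeSystem])
            if bad_sys.any():
                row = int(np.argmax(bad_sys.to_numpy()))
                raise ClaimsError(f"event row {row}: unknown code system")
            if (events["code"] == "").any():
                raise ClaimsError("empty event code")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls, patients: Iterable[PatientRecord], events: Iterable[ClaimEvent]
    ) -> "ClaimsDatabase":
        pdf = pd.DataFrame(
            [
                (p.patient_id, p.sex, p.birth_ym, p.enroll_start, p.enroll_end)
                for p in patients
            ],
            columns=PATIENT_COLUMNS,
        )
        edf = pd.DataFrame(
            [(e.patient_id, e.date, e.system.value, normalize_code(e.code)) for e in events],
            columns=EVENT_COLUMNS,
        )
        return cls(pdf, edf)

    # -- access -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.patients)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClaimsDatabase):
            return NotImplemented
        return self.patients.equals(other.patients) and self.events.equals(other.events)

    def patient_ids(self) -> list[str]:
        return self.patients["patient_id"].tolist()

    def has_patient(self, patient_id: str) -> bool:
        return patient_id in set(self.patients["patient_id"])

    def _slices(self) -> dict[str, slice]:
        # events are sorted by patient_id, so each patient's rows are contiguous
        if self._event_slices is None:
            pid = self.events["patient_id"].to_numpy()
            slices: dict[str, slice] = {}
            if len(pid):
                change = np.flatnonzero(pid[1:] != pid[:-1]) + 1
                starts = np.concatenate([[0], change])
                ends = np.concatenate([change, [len(pid)]])
                slices = {pid[s]: slice(int(s), int(e)) for s, e in zip(starts, ends)}
            self._event_slices = slices
        return self._event_slices

    def events_for(self, patient_id: str) -> pd.DataFrame:
        if not self.has_patient(patient_id):
            raise KeyError(f"unknown patient {patient_id!r}")
        sl = self._slices().get(patient_id)
        if sl is None:
            return self.events.iloc[0:0]
        return self.events.iloc[sl]

    def events_in_window(
        self,
        patient_id: str,
        code_set: CodeSet,
        window_start: dt.date,
        window_end: dt.date,
    ) -> pd.DataFrame:
        """Matching events of a patient with window_start <= date < window_end."""
        if window_start > window_end:
            raise ValueError("window_start must not exceed window_end")
        ev = self.events_for(patient_id)
        ev = ev[ev["system"] == code_set.system.value]
        if not len(ev):
            return ev
        start = pd.Timestamp(window_start)
        end = pd.Timestamp(window_end)
        ev = ev[(ev["date"] >= start) & (ev["date"] < end)]
        if not len(ev):
            return ev
        return ev[code_set.mask(ev["code"])]


def events_in_window(
    db: ClaimsDatabase,
    patient_id: str,
    code_set: CodeSet,
    window_start: dt.date,
    window_end: dt.date,
) -> list[ClaimEvent]:
    """Functional wrapper returning ClaimEvent objects in date order."""
    rows = db.events_in_window(patient_id, code_set, window_start, window_end)
    return [
        ClaimEvent(r.patient_id, r.date.date(), CodeSystem(r.system), r.code)
        for r in rows.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# CSV dialect
#
# patients.csv: patient_id, sex (M/F), birth_ym (YYYY-MM),
#               enroll_start (YYYY-MM-DD), enroll_end (YYYY-MM-DD)
# events.csv:   patient_id, date (YYYY-MM-DD), system, code


def read_claims(patient_path: str | Path, event_path: str | Path) -> ClaimsDatabase:
    pdf = pd.read_csv(patient_path, dtype=str, keep_default_na=False)
    edf = pd.read_csv(event_path, dtype=str, keep_default_na=False)
    for col in PATIENT_COLUMNS:
        if col not in pdf.columns:
            raise ClaimsError(f"{patient_path}: missing column {col!r}")
    for col in EVENT_COLUMNS:
        if col not in edf.columns:
            raise ClaimsError(f"{event_path}: missing column {col!r}")

    def _parse_dates(s: pd.Series, fmt: str, what: str) -> pd.Series:
        parsed = pd.to_datetime(s, format=fmt, errors="coerce")
        bad = parsed.isna() & (s != "")
        if bad.any():
            row = int(np.argmax(bad.to_numpy())) + 2  # header is line 1
            raise ClaimsError(f"unparseable {what} at line {row}: {s[bad].iloc[0]!r}")
        if parsed.isna().any():
            row = int(np.argmax(parsed.isna().to_numpy())) + 2
            raise ClaimsError(f"missing {what} at line {row}")
        return parsed

    if len(pdf):
        pdf["birth_ym"] = _parse_dates(pdf["birth_ym"], "%Y-%m", "birth_ym")
        pdf["enroll_start"] = _parse_dates(pdf["enroll_start"], "%Y-%m-%d", "enroll_start")
        pdf["enroll_end"] = _parse_dates(pdf["enroll_end"], "%Y-%m-%d", "enroll_end")
    else:
        for col in ("birth_ym", "enroll_start", "enroll_end"):
            pdf[col] = pd.Series([], dtype="datetime64[ns]")
    if len(edf):
        edf["date"] = _parse_dates(edf["date"], "%Y-%m-%d", "event date")
    try:
        return ClaimsDatabase(pdf, edf)
    except ClaimsError:
        raise


def write_claims(
    db: ClaimsDatabase, patient_path: str | Path, event_path: str | Path
) -> None:
    pdf = db.patients.copy()
    pdf["birth_ym"] = pdf["birth_ym"].dt.strftime("%Y-%m")
    pdf["enroll_start"] = pdf["enroll_start"].dt.strftime("%Y-%m-%d")
    pdf["enroll_end"] = pdf["enroll_end"].dt.strftime("%Y-%m-%d")
    pdf[PATIENT_COLUMNS].to_csv(patient_path, index=False)
    edf = db.events.copy()
    edf["date"] = edf["date"].dt.strftime("%Y-%m-%d")
    edf[EVENT_COLUMNS].to_csv(event_path, index=False)
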