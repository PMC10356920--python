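import datetime as dt

import pytest

from oagncc import (
    ClaimEvent,
    ClaimsDatabase,
    CodeSystem,
    PatientRecord,
    SimulationConfig,
    load_code_config,
    simulate,
)


@pytest.fixture(scope="session")
def code_config():
    return load_code_config()


def make_patient(pid="P1", sex="M", birth=dt.date(1970, 1, 1),
                 start=dt.date(2008, 1, 1), end=dt.date(2015, 1, 1)):
    return PatientRecord(pid, sex, birth, start, end)


def ev(pid, date, system, code):
    return ClaimEvent(pid, date, CodeSystem(system), code)


@pytest.fixture()
def tiny_db():
    """Three patients with a handful of hand-placed events."""
    patients = [
        make_patient("P1"),
        make_patient("P2", sex="F", birth=dt.date(1980, 6, 1)),
        make_patient("P3", birth=dt.date(1955, 3, 1)),
    ]
    events = [
        ev("P1", dt.date(2010, 3, 1), "ICD10", "E78"),
        ev("P1", dt.date(2010, 5, 1), "ICD10", "E780"),
        ev("P1", dt.date(2011, 1, 1), "ATC_EPHMRA", "C10A11"),
        ev("P2", dt.date(2012, 2, 15), "ICD10", "H401"),
        ev("P2", dt.date(2012, 2, 15), "ATC_EPHMRA", "S1E2"),
        ev("P3", dt.date(2013, 7, 1), "JP_PROCEDURE", "K268"),
    ]
    return ClaimsDatabase.from_records(patients, events)


@pytest.fixture(scope="session")
def sim_small(code_config):
    """Mid-sized seeded simulation reused across cohort/matching tests."""
    cfg = SimulationConfig(n_patients=800, seed=11)
    db, truth = simulate(cfg, code_config)
    return cfg, db, truth


@pytest.fixture(scope="session")
def null_sim(code_config):
    """Large simulation with all true effects zero, for marginal checks."""
    lor = {k: 0.0 for k in SimulationConfig().log_or}
    cfg = SimulationConfig(n_patients=5000, seed=202, log_or=lor)
    db, truth = simulate(cfg, code_config)
    return cfg, db, truth
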