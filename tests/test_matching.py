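import datetime as dt

import pandas as pd
import pytest

from conftest import ev, make_patient
from oracles import brute_force_eligibility, verify_matched_set

from oagncc import (
    MODEL1,
    ClaimsDatabase,
    MatchingParams,
    SimulationConfig,
    build_cohort,
    eligible_controls,
    find_index_date,
    sample_matched_sets,
    sets_to_frame,
    simulate,
)


class TestFindIndexDate:
    def _db(self, events):
        return ClaimsDatabase.from_records([make_patient("P1")], events)

    def test_earliest_channel_wins(self, code_config):
        db = self._db(
            [
                ev("P1", dt.date(2012, 5, 1), "ATC_EPHMRA", "S1E2"),
                ev("P1", dt.date(2013, 1, 1), "ICD10", "H401"),
            ]
        )
        hit = find_index_date(db, "P1", code_config)
        assert hit.index_date == dt.date(2012, 5, 1)
        assert hit.channel == "drug"

    def test_surgery_only(self, code_config):
        db = self._db([ev("P1", dt.date(2014, 2, 1), "JP_PROCEDURE", "K268")])
        hit = find_index_date(db, "P1", code_config)
        assert (hit.index_date, hit.channel) == (dt.date(2014, 2, 1), "surgery")

    def test_same_day_tie_prefers_diagnosis(self, code_config):
        db = self._db(
            [
                ev("P1", dt.date(2012, 5, 1), "ATC_EPHMRA", "S1E2"),
                ev("P1", dt.date(2012, 5, 1), "ICD10", "H406"),
            ]
        )
        assert find_index_date(db, "P1", code_config).channel == "diagnosis"

    def test_no_outcome_returns_none(self, code_config, tiny_db):
        assert find_index_date(tiny_db, "P1", code_config) is None


def _cohort_frame(rows):
    """rows: (pid, sex, age, entry, obs_months, duration_to_index)."""
    return pd.DataFrame(
        [
            {
                "patient_id": pid,
                "sex": sex,
                "entry_date": pd.Timestamp(entry),
                "age_at_entry": age,
                "last_dyslipidemia_date": pd.Timestamp(entry) + pd.DateOffset(months=obs),
                "index_date": pd.Timestamp(entry) + pd.DateOffset(months=dur)
                if dur >= 0
                else pd.NaT,
                "index_channel": "diagnosis" if dur >= 0 else None,
                "observation_end": pd.Timestamp(entry) + pd.DateOffset(months=min(obs, dur) if dur >= 0 else obs),
                "observation_months": obs,
                "duration_to_index": dur,
            }
            for pid, sex, age, entry, obs, dur in rows
        ]
    )


class TestEligibleControls:
    base = ("C0", "M", 50, dt.date(2010, 6, 1), 24, 24)

    def test_predicates(self):
        rows = [
            self.base,
            ("A_sex", "F", 50, dt.date(2010, 6, 1), 30, -1),
            ("B_age", "M", 56, dt.date(2010, 6, 1), 30, -1),
            ("C_entry", "M", 50, dt.date(2010, 10, 1), 30, -1),
            ("D_short", "M", 50, dt.date(2010, 6, 1), 20, -1),
            ("E_ok", "M", 50, dt.date(2010, 8, 1), 24, -1),
            ("F_future_case", "M", 48, dt.date(2010, 5, 1), 30, 30),
            ("G_earlier_case", "M", 50, dt.date(2010, 6, 1), 20, 20),
        ]
        got = eligible_controls("C0", _cohort_frame(rows))
        assert got == ["E_ok", "F_future_case"]

    def test_case_never_its_own_control(self):
        got = eligible_controls("C0", _cohort_frame([self.base, self.base[:1] + self.base[1:]]))
        assert "C0" not in got

    def test_non_case_rejected(self):
        frame = _cohort_frame([("X", "M", 50, dt.date(2010, 6, 1), 24, -1)])
        with pytest.raises(ValueError):
            eligible_controls("X", frame)


class TestSampleMatchedSets:
    def _frame_with_pool(self, pool_size):
        rows = [("CASE", "M", 50, dt.date(2010, 6, 1), 24, 24)]
        rows += [
            (f"K{i:02d}", "M", 50, dt.date(2010, 6, 1), 36, -1) for i in range(pool_size)
        ]
        return _cohort_frame(rows)

    @pytest.mark.parametrize("pool,expected", [(12, 10), (4, 4)])
    def test_maximum_controls_semantics(self, pool, expected):
        sets, log = sample_matched_sets(self._frame_with_pool(pool), MatchingParams(seed=7))
        assert len(sets) == 1
        assert len(sets[0].control_ids) == expected
        assert len(set(sets[0].control_ids)) == expected

    def test_zero_pool_drops_case_into_log(self):
        sets, log = sample_matched_sets(self._frame_with_pool(0), MatchingParams(seed=7))
        assert sets == []
        assert log.dropped_cases == ["CASE"]

    def test_seeded_determinism_and_row_order_invariance(self):
        frame = self._frame_with_pool(30)
        a, _ = sample_matched_sets(frame, MatchingParams(seed=7))
        b, _ = sample_matched_sets(frame, MatchingParams(seed=7))
        shuffled = frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        c, _ = sample_matched_sets(shuffled, MatchingParams(seed=7))
        assert a == b == c
        d, _ = sample_matched_sets(frame, MatchingParams(seed=8))
        assert a != d  # different stream actually changes the draw

    def test_control_reuse_across_sets_under_small_pools(self):
        rows = [
            ("CASE1", "M", 50, dt.date(2010, 6, 1), 24, 24),
            ("CASE2", "M", 50, dt.date(2010, 6, 1), 30, 30),
            ("K1", "M", 50, dt.date(2010, 6, 1), 40, -1),
        ]
        sets, _ = sample_matched_sets(_cohort_frame(rows), MatchingParams(seed=1))
        assert len(sets) == 2
        assert all(s.control_ids.count("K1") == 1 or "K1" in s.control_ids for s in sets)
        # K1 appears in both sets: reuse with replacement across sets
        assert sum("K1" in s.control_ids for s in sets) == 2


class TestSamplerAgainstOracle:
    def test_every_control_passes_all_predicates(self, sim_small, code_config):
        db = sim_small[1]
        cohort, _ = build_cohort(db, MODEL1, code_config)
        sets, log = sample_matched_sets(cohort, MatchingParams(seed=99))
        assert len(sets) > 10
        oracle = brute_force_eligibility(db, 12)
        recs = {p: r for p, (s, r) in oracle.items() if s is None}
        violations = []
        for s in sets:
            case = recs[s.case_id]
            assert case["is_case"]
            violations += verify_matched_set(case, {c: recs[c] for c in s.control_ids})
        assert violations == []
        # shared index date and duration bookkeeping
        frame = sets_to_frame(sets)
        per_set = frame.groupby("set_id")["index_date"].nunique()
        assert (per_set == 1).all()
        assert frame.groupby("set_id")["patient_id"].apply(lambda s: s.is_unique).all()
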