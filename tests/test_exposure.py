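import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ev, make_patient

from oagncc import (
    MODEL1,
    ClaimsDatabase,
    MatchingParams,
    assess_covariates,
    build_cohort,
    classify_exposure,
    count_statin_prescriptions,
    covariate_table,
    exposure_thresholds,
    sample_matched_sets,
    sets_to_frame,
    simulate,
)
from oagncc.exposure import SUBSTANCES, count_statins_bulk


class TestThresholds:
    def test_nearest_rank_examples(self):
        th = exposure_thresholds([5, 7, 9, 11], "model1")
        assert (th.q1, th.q2) == (5, 7)

    def test_all_equal_counts(self):
        th = exposure_thresholds([6] * 8, "model1")
        assert (th.q1, th.q2) == (6, 6)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exposure_thresholds([], "model1")

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=200), st.integers(0, 2**31 - 1))
    def test_matches_sort_and_index_oracle_and_permutation_invariance(self, counts, seed):
        th = exposure_thresholds(counts, "model1")
        s = sorted(counts)
        n = len(s)
        assert th.q1 == s[max(math.ceil(0.25 * n), 1) - 1]
        assert th.q2 == s[max(math.ceil(0.50 * n), 1) - 1]
        perm = list(np.random.default_rng(seed).permutation(counts))
        th2 = exposure_thresholds(perm, "model1")
        assert (th.q1, th.q2) == (th2.q1, th2.q2)
        assert th.q1 <= th.q2


class TestCountPrescriptions:
    def _db(self, dates, code="C10A11"):
        return ClaimsDatabase.from_records(
            [make_patient("P1")],
            [ev("P1", d, "ATC_EPHMRA", code) for d in dates],
        )

    def test_prescription_on_index_date_not_counted(self, code_config):
        idx = dt.date(2012, 6, 1)
        db = self._db([idx, dt.date(2012, 5, 1)])
        total, per = count_statin_prescriptions(db, "P1", idx, 12, code_config)
        assert total == 1
        assert per["rosuvastatin"] == 1

    def test_partial_refill_months(self, code_config):
        idx = dt.date(2012, 6, 1)
        dates = [dt.date(2011, 7 + k, 1) for k in range(6)] + [dt.date(2012, 2, 1)]
        total, _ = count_statin_prescriptions(self._db(dates), "P1", idx, 12, code_config)
        assert total == 7

    def test_window_start_boundary_included(self, code_config):
        idx = dt.date(2012, 6, 1)
        total, _ = count_statin_prescriptions(
            self._db([dt.date(2011, 6, 1)]), "P1", idx, 12, code_config
        )
        assert total == 1
        total24, _ = count_statin_prescriptions(
            self._db([dt.date(2011, 5, 31)]), "P1", idx, 24, code_config
        )
        assert total24 == 1

    def test_bulk_counts_equal_scalar_counts(self, sim_small, code_config):
        db = sim_small[1]
        cohort, _ = build_cohort(db, MODEL1, code_config)
        sets, _ = sample_matched_sets(cohort, MatchingParams(seed=4))
        members = sets_to_frame(sets).head(120)
        bulk = count_statins_bulk(db, members, 12, code_config)
        for row in bulk.itertuples(index=False):
            total, per = count_statin_prescriptions(
                db, row.patient_id, row.index_date.date(), 12, code_config
            )
            assert row.total_count == total
            for s in SUBSTANCES:
                assert getattr(row, s) == per[s]


class TestClassification:
    def _record(self, total, ros=0):
        per = {s: 0 for s in SUBSTANCES}
        per["rosuvastatin"] = ros if ros else total
        th = exposure_thresholds([5, 7, 9, 11], "model1")  # q1=5, q2=7
        return classify_exposure("P", 0, total, per, th)

    @pytest.mark.parametrize("total,q1,q2", [(5, True, False), (4, False, False), (7, True, True), (0, False, False)])
    def test_threshold_boundaries(self, total, q1, q2):
        r = self._record(total)
        assert (r.exposed_q1, r.exposed_q2) == (q1, q2)

    def test_q2_implies_q1_on_random_counts(self):
        rng = np.random.default_rng(0)
        th = exposure_thresholds(list(rng.integers(1, 30, size=50)), "model1")
        for total in rng.integers(0, 35, size=200):
            per = {s: 0 for s in SUBSTANCES}
            per["fluvastatin"] = int(total)
            r = classify_exposure("P", 0, int(total), per, th)
            assert not (r.exposed_q2 and not r.exposed_q1)

    def test_total_must_equal_substance_sum(self):
        th = exposure_thresholds([5], "model1")
        with pytest.raises(ValueError):
            classify_exposure("P", 0, 3, {s: 0 for s in SUBSTANCES}, th)


class TestCovariates:
    entry = dt.date(2012, 6, 1)

    def _flags(self, events, code_config):
        db = ClaimsDatabase.from_records([make_patient("P1")], events)
        return assess_covariates(db, "P1", self.entry, code_config)

    def test_single_diagnosis_insufficient(self, code_config):
        flags = self._flags([ev("P1", dt.date(2012, 3, 1), "ICD10", "E11")], code_config)
        assert not flags["diabetes_mellitus"]

    def test_two_codes_same_date_insufficient(self, code_config):
        flags = self._flags(
            [
                ev("P1", dt.date(2012, 3, 1), "ICD10", "E11"),
                ev("P1", dt.date(2012, 3, 1), "ICD10", "E14"),
            ],
            code_config,
        )
        assert not flags["diabetes_mellitus"]

    def test_two_distinct_dates_qualify(self, code_config):
        flags = self._flags(
            [
                ev("P1", dt.date(2012, 1, 15), "ICD10", "E11"),
                ev("P1", dt.date(2012, 4, 1), "ICD10", "E149"),
            ],
            code_config,
        )
        assert flags["diabetes_mellitus"]

    def test_single_steroid_prescription_qualifies(self, code_config):
        flags = self._flags([ev("P1", dt.date(2012, 2, 1), "ATC_EPHMRA", "H2")], code_config)
        assert flags["steroid"]

    def test_events_on_or_after_entry_ignored(self, code_config):
        flags = self._flags(
            [
                ev("P1", self.entry, "ICD10", "E11"),
                ev("P1", dt.date(2012, 8, 1), "ICD10", "E11"),
            ],
            code_config,
        )
        assert not flags["diabetes_mellitus"]

    def test_composite_requires_two_dates_within_one_group(self, code_config):
        mixed = self._flags(
            [
                ev("P1", dt.date(2012, 2, 1), "ICD10", "M352"),
                ev("P1", dt.date(2012, 4, 1), "ICD10", "B00"),
            ],
            code_config,
        )
        assert not mixed["infectious_inflammatory"]
        same = self._flags(
            [
                ev("P1", dt.date(2012, 2, 1), "ICD10", "M352"),
                ev("P1", dt.date(2012, 4, 1), "ICD10", "M352"),
            ],
            code_config,
        )
        assert same["infectious_inflammatory"]

    def test_table_matches_scalar_assessment(self, sim_small, code_config):
        db, truth = sim_small[1], sim_small[2]
        sub = db.patients.head(60)
        frame = pd.DataFrame(
            {
                "patient_id": sub["patient_id"],
                "entry_date": truth.set_index("patient_id").loc[
                    sub["patient_id"], "onset_date"
                ].to_numpy(),
            }
        )
        table = covariate_table(db, frame, code_config).set_index("patient_id")
        for row in frame.itertuples(index=False):
            scalar = assess_covariates(db, row.patient_id, row.entry_date.date(), code_config)
            assert scalar == table.loc[row.patient_id].to_dict()
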