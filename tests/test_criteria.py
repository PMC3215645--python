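"""Gold-standard rule engines: diagnostic criteria, eligibility, BP summaries."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, strategies as st

from phenoval import (
    Status,
    classify_dm,
    classify_htn,
    dm_eligible,
    htn_eligible,
    summarize_bp_visits,
)

from conftest import make_patient


class TestDMEligibility:
    def test_one_glucose_suffices(self):
        assert dm_eligible(make_patient(fasting=(100.0,)))

    def test_no_glucose_no_meds_is_ineligible(self):
        assert not dm_eligible(make_patient())

    def test_therapy_plus_history_needs_no_lab(self):
        b = make_patient(meds=("antidiabetic",), history=("DM",))
        assert dm_eligible(b)
        assert classify_dm(b).status is Status.POSITIVE

    def test_therapy_without_history_insufficient(self):
        assert not dm_eligible(make_patient(meds=("antidiabetic",)))


class TestClassifyDM:
    @pytest.mark.parametrize(
        "kwargs, expected_status, expected_criterion",
        [
            # fasting threshold is inclusive
            (dict(fasting=(126.0,)), Status.POSITIVE, "FPG>=126"),
            (dict(fasting=(125.9,)), Status.NEGATIVE, None),
            # symptomatic random glucose
            (dict(random_glucose=(210.0,), hyperglycemia_symptoms_flag=True),
             Status.POSITIVE, "symptoms+random>=200"),
            (dict(random_glucose=(210.0,)), Status.NEGATIVE, None),
            # 75-g OGTT 2-h value
            (dict(ogtt75=(200.0,)), Status.POSITIVE, "OGTT75_2h>=200"),
            (dict(ogtt75=(199.0,)), Status.NEGATIVE, None),
            # gestational pattern: at least two of four points
            (dict(ogtt100=(96.0, 181.0, 150.0, 120.0), pregnant_flag=True),
             Status.POSITIVE, "GDM_OGTT100"),
            (dict(ogtt100=(96.0, 179.0, 150.0, 120.0), pregnant_flag=True),
             Status.NEGATIVE, None),
            # two points met but not pregnant
            (dict(ogtt100=(96.0, 181.0, 150.0, 120.0)), Status.NEGATIVE, None),
            # therapy + gestational history
            (dict(meds=("antidiabetic",), history=("GDM",), fasting=(100.0,)),
             Status.POSITIVE, "GDM_therapy+history"),
        ],
    )
    def test_examples(self, kwargs, expected_status, expected_criterion):
        result = classify_dm(make_patient(**kwargs))
        assert result.status is expected_status
        if expected_criterion:
            assert expected_criterion in result.fired_criteria
        if expected_status is Status.POSITIVE:
            assert result.fired_criteria
        else:
            assert not result.fired_criteria

    def test_no_records_is_ineligible(self):
        assert classify_dm(make_patient()).status is Status.INELIGIBLE

    def test_gdm_points_must_share_a_test_date(self):
        import datetime as dt
        from phenoval import GlucoseMeasurement

        b = make_patient(pregnant_flag=True)
        b.glucose.append(GlucoseMeasurement(dt.date(2009, 1, 1), "ogtt100_fasting", 100.0))
        b.glucose.append(GlucoseMeasurement(dt.date(2009, 5, 1), "ogtt100_1h", 190.0))
        assert classify_dm(b).status is Status.NEGATIVE

    def test_order_invariant_over_record_lists(self):
        b = make_patient(fasting=(100.0, 130.0, 90.0), random_glucose=(150.0,),
                         meds=("antidiabetic",), history=("DM",))
        reference = classify_dm(b)
        rng = random.Random(0)
        for _ in range(5):
            rng.shuffle(b.glucose)
            rng.shuffle(b.medications)
            rng.shuffle(b.history_notes)
            again = classify_dm(b)
            assert again.status is reference.status
            assert set(again.fired_criteria) == set(reference.fired_criteria)

    @given(values=st.lists(st.floats(50.0, 400.0), min_size=1, max_size=4),
           bump=st.floats(0.0, 500.0))
    def test_monotone_in_glucose(self, values, bump):
        """Raising any glucose value never flips positive to negative."""
        before = classify_dm(make_patient(fasting=tuple(values)))
        raised = tuple(min(v + bump, 1400.0) for v in values)
        after = classify_dm(make_patient(fasting=raised))
        if before.status is Status.POSITIVE:
            assert after.status is Status.POSITIVE


class TestBPVisitSummaries:
    def test_arithmetic_mean_per_visit(self):
        import datetime as dt
        from phenoval import BPReading, PatientBundle

        b = PatientBundle("p", "male", 50)
        b.bp.append(BPReading("v1", dt.date(2009, 1, 1), 142.0, 92.0))
        b.bp.append(BPReading("v1", dt.date(2009, 1, 1), 138.0, 88.0))
        (summary,) = summarize_bp_visits(b)
        assert summary.mean_systolic == pytest.approx(140.0)
        assert summary.mean_diastolic == pytest.approx(90.0)
        assert summary.n_readings == 2

    def test_one_summary_per_visit(self):
        b = make_patient(visits=((150.0, 95.0), (120.0, 70.0)))
        assert [s.visit_id for s in summarize_bp_visits(b)] == ["p1-v0", "p1-v1"]

    def test_no_readings_empty_list(self):
        assert summarize_bp_visits(make_patient()) == []


class TestHTNEligibility:
    def test_two_visits_eligible(self):
        assert htn_eligible(make_patient(visits=((120.0, 70.0), (118.0, 72.0))))

    def test_single_visit_not_eligible_even_with_many_readings(self):
        b = make_patient(visits=((150.0, 95.0),), readings_per_visit=3)
        assert not htn_eligible(b)
        assert classify_htn(b, dm_status=False).status is Status.INELIGIBLE

    def test_therapy_plus_history_needs_no_readings(self):
        b = make_patient(meds=("antihypertensive",), history=("HTN",))
        assert htn_eligible(b)
        result = classify_htn(b, dm_status=False)
        assert result.status is Status.POSITIVE
        assert "antihypertensive+history" in result.fired_criteria


class TestClassifyHTN:
    @pytest.mark.parametrize(
        "visits, dm_status, ckd, expected",
        [
            # non-diabetic at the 140/90 thresholds
            (((142.0, 80.0), (145.0, 82.0)), False, False, Status.POSITIVE),
            (((138.0, 85.0), (139.0, 86.0)), False, False, Status.NEGATIVE),
            # diabetic: 130/80 applies
            (((132.0, 78.0), (134.0, 76.0)), True, False, Status.POSITIVE),
            (((132.0, 78.0), (134.0, 76.0)), False, False, Status.NEGATIVE),
            # chronic kidney disease alone lowers the threshold too
            (((132.0, 78.0), (134.0, 76.0)), False, True, Status.POSITIVE),
            # diastolic criterion alone can fire
            (((120.0, 92.0), (118.0, 94.0)), False, False, Status.POSITIVE),
            # grand mean across visits decides: (142 + 136)/2 = 139 < 140
            (((142.0, 80.0), (136.0, 82.0)), False, False, Status.NEGATIVE),
        ],
    )
    def test_examples(self, visits, dm_status, ckd, expected):
        b = make_patient(visits=visits, ckd_flag=ckd)
        assert classify_htn(b, dm_status=dm_status).status is expected

    def test_threshold_is_inclusive(self):
        b = make_patient(visits=((140.0, 70.0), (140.0, 72.0)))
        assert classify_htn(b, dm_status=False).status is Status.POSITIVE

    @given(
        sys_means=st.lists(st.floats(100.0, 200.0), min_size=2, max_size=4),
        dia_offset=st.floats(30.0, 59.0),
    )
    def test_dm_threshold_dominates(self, sys_means, dia_offset):
        """A patient positive under 140/90 stays positive under 130/80."""
        visits = tuple((s, s - dia_offset) for s in sys_means)
        b = make_patient(visits=visits)
        if classify_htn(b, dm_status=False).status is Status.POSITIVE:
            assert classify_htn(b, dm_status=True).status is Status.POSITIVE

    @given(
        sys_means=st.lists(st.floats(100.0, 180.0), min_size=2, max_size=3),
        bump=st.floats(0.0, 80.0),
    )
    def test_monotone_in_bp(self, sys_means, bump):
        visits = tuple((s, 60.0) for s in sys_means)
        before = classify_htn(make_patient(visits=visits), dm_status=False)
        raised = tuple((s + bump, 60.0) for s in sys_means)
        after = classify_htn(make_patient(visits=raised), dm_status=False)
        if before.status is Status.POSITIVE:
            assert after.status is Status.POSITIVE
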