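"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import datetime as dt

import pytest
from hypothesis import settings

from phenoval import (
    BPReading,
    Cohort,
    Episode,
    GlucoseMeasurement,
    HistoryNote,
    MedicationRecord,
    PatientBundle,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

D = dt.date(2009, 6, 1)


def make_patient(
    pid: str = "p1",
    sex: str = "female",
    age: int = 60,
    codes: tuple[str, ...] = (),
    fasting: tuple[float, ...] = (),
    random_glucose: tuple[float, ...] = (),
    ogtt75: tuple[float, ...] = (),
    ogtt100: tuple[float, float, float, float] | None = None,
    visits: tuple[tuple[float, float], ...] = (),
    readings_per_visit: int = 2,
    meds: tuple[str, ...] = (),
    history: tuple[str, ...] = (),
    **flags,
) -> PatientBundle:
    """Build a patient whose records produce the requested measurements.

    ``visits`` gives per-visit (systolic, diastolic) means; each visit gets
    ``readings_per_visit`` identical readings so the per-visit mean is exact.
    """
    b = PatientBundle(patient_id=pid, sex=sex, age=age, **flags)
    for code in codes:
        b.episodes.append(Episode(code, "episode", D))
    for v in fasting:
        b.glucose.append(GlucoseMeasurement(D, "fasting", v))
    for v in random_glucose:
        b.glucose.append(GlucoseMeasurement(D, "random", v))
    for v in ogtt75:
        b.glucose.append(GlucoseMeasurement(D, "ogtt75_2h", v))
    if ogtt100 is not None:
        for kind, v in zip(
            ("ogtt100_fasting", "ogtt100_1h", "ogtt100_2h", "ogtt100_3h"), ogtt100
        ):
            b.glucose.append(GlucoseMeasurement(D, kind, v))
    for k, (sys, dia) in enumerate(visits):
        for _ in range(readings_per_visit):
            b.bp.append(BPReading(f"{pid}-v{k}", D, sys, dia))
    for drug in meds:
        b.medications.append(MedicationRecord(D, drug))
    for cond in history:
        b.history_notes.append(HistoryNote(cond, D))
    return b


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Three patients, one of whom has two glucose entries."""
    return Cohort(
        [
            make_patient("a1", "male", 55, codes=("T90",), fasting=(180.0, 140.0)),
            make_patient("a2", "female", 72, codes=("K86",), visits=((150.0, 95.0), (148.0, 92.0))),
            make_patient("a3", "female", 40),
        ],
        provenance="fixture",
    )
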