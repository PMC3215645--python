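"""Domain model for primary-care computerized-clinical-record extracts.

The unit of analysis is a :class:`PatientBundle`: one patient's demographics
and clinical flags together with their coded episodes (ICPC), plasma-glucose
measurements, per-visit blood-pressure readings, medication records and
structured history notes.  A :class:`Cohort` is a collection of bundles with
unique patient ids.

Conventions
-----------
* Dates are calendar dates (day granularity); visit times are not modelled.
* Glucose is plasma glucose in mg/dl; blood pressure in mmHg.
* Age is the attained age (integer years) at the extract's index date, so no
  birth-date arithmetic happens downstream.
* The free-text "previous diagnosis in medical records" concept is modelled
  as a structured :class:`HistoryNote`; free-text parsing is out of scope.
* Chronic kidney disease is a boolean patient flag (it is only ever used to
  select the lower blood-pressure threshold).
"""

from __future__ import annotations

import datetime as _dt
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Sex",
    "GlucoseKind",
    "DrugClass",
    "Condition",
    "Episode",
    "GlucoseMeasurement",
    "BPReading",
    "MedicationRecord",
    "HistoryNote",
    "PatientBundle",
    "Cohort",
    "has_code",
    "DM_CODES",
    "HTN_CODES",
    "RecordValidationError",
]

#: ICPC episode codes for diabetes mellitus and hypertension.
DM_CODES = frozenset({"T90"})
HTN_CODES = frozenset({"K86", "K87"})

_ICPC_RE = re.compile(r"^[A-Z]\d{2}$")


class RecordValidationError(ValueError):
    """A record violates a domain invariant."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class GlucoseKind(str, enum.Enum):
    """Type of plasma-glucose determination.

    ``fasting`` and ``random`` are single venous samples; ``ogtt75_2h`` is the
    2-hour value of a 75-g oral glucose tolerance test; the four ``ogtt100_*``
    kinds are the fasting/1-h/2-h/3-h points of the 100-g test used for
    gestational diabetes.
    """

    FASTING = "fasting"
    RANDOM = "random"
    OGTT75_2H = "ogtt75_2h"
    OGTT100_FASTING = "ogtt100_fasting"
    OGTT100_1H = "ogtt100_1h"
    OGTT100_2H = "ogtt100_2h"
    OGTT100_3H = "ogtt100_3h"


class DrugClass(str, enum.Enum):
    ANTIDIABETIC = "antidiabetic"
    ANTIHYPERTENSIVE = "antihypertensive"
    OTHER = "other"


class Condition(str, enum.Enum):
    DM = "DM"
    GDM = "GDM"
    HTN = "HTN"


@dataclass(frozen=True, slots=True)
class Episode:
    """A coded problem/episode on the patient's episode list."""

    icpc_code: str
    label: str
    date: _dt.date

    def __post_init__(self) -> None:
        if not self.icpc_code or not _ICPC_RE.match(self.icpc_code):
            raise RecordValidationError(
                f"icpc_code must be a letter plus two digits, got {self.icpc_code!r}"
            )


@dataclass(frozen=True, slots=True)
class GlucoseMeasurement:
    date: _dt.date
    kind: GlucoseKind
    value: float  # mg/dl

    def __post_init__(self) -> None:
        if not isinstance(self.kind, GlucoseKind):
            object.__setattr__(self, "kind", GlucoseKind(self.kind))
        if not (10.0 < self.value < 1500.0):
            raise RecordValidationError(
                f"glucose value {self.value} mg/dl outside plausibility window (10, 1500)"
            )


@dataclass(frozen=True, slots=True)
class BPReading:
    visit_id: str
    date: _dt.date
    systolic: float  # mmHg
    diastolic: float  # mmHg

    def __post_init__(self) -> None:
        if not (40.0 <= self.diastolic < self.systolic <= 300.0):
            raise RecordValidationError(
                f"BP reading {self.systolic}/{self.diastolic} violates "
                "40 <= diastolic < systolic <= 300"
            )


@dataclass(frozen=True, slots=True)
class MedicationRecord:
    date: _dt.date
    drug_class: DrugClass

    def __post_init__(self) -> None:
        if not isinstance(self.drug_class, DrugClass):
            object.__setattr__(self, "drug_class", DrugClass(self.drug_class))


@dataclass(frozen=True, slots=True)
class HistoryNote:
    """A structured mention of a prior diagnosis in the medical record."""

    condition: Condition
    date: _dt.date

    def __post_init__(self) -> None:
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))


@dataclass(slots=True)
class PatientBundle:
    """One patient's longitudinal record."""

    patient_id: str
    sex: Sex
    age: int
    ckd_flag: bool = False
    pregnant_flag: bool = False
    hyperglycemia_symptoms_flag: bool = False
    episodes: list[Episode] = field(default_factory=list)
    glucose: list[GlucoseMeasurement] = field(default_factory=list)
    bp: list[BPReading] = field(default_factory=list)
    medications: list[MedicationRecord] = field(default_factory=list)
    history_notes: list[HistoryNote] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not isinstance(self.sex, Sex):
            self.sex = Sex(self.sex)
        if not self.patient_id:
            raise RecordValidationError("patient_id must be non-empty")
        if self.age < 0:
            raise RecordValidationError(f"age must be >= 0, got {self.age}")


class Cohort:
    """A collection of patient bundles with unique patient ids."""

    def __init__(self, patients: Iterable[PatientBundle], provenance: str = "") -> None:
        self.patients: list[PatientBundle] = list(patients)
        self.provenance = provenance
        self._index: dict[str, PatientBundle] = {}
        for p in self.patients:
            if p.patient_id in self._index:
                raise RecordValidationError(f"duplicate patient_id {p.patient_id!r}")
            self._index[p.patient_id] = p

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self) -> Iterator[PatientBundle]:
        return iter(self.patients)

    def __contains__(self, patient_id: str) -> bool:
        return patient_id in self._index

    def get(self, patient_id: str) -> PatientBundle:
        try:
            return self._index[patient_id]
        except KeyError:
            raise KeyError(f"unknown patient_id {patient_id!r}") from None


def has_code(bundle: PatientBundle, code_set: Iterable[str]) -> bool:
    """True iff any episode on the bundle carries an ICPC code in ``code_set``.

    This is the "diagnostic test" side of the validation: carrying, e.g., a
    T90 episode marks the patient as code-positive for diabetes regardless of
    what the raw measurements show.
    """
    codes = frozenset(code_set)
    if not codes:
        raise ValueError("code_set must be non-empty")
    return any(ep.icpc_code in codes for ep in bundle.episodes)
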