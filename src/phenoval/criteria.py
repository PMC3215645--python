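"""Gold-standard diagnostic rule engines.

Diabetes mellitus follows the ADA 2003 consensus criteria; hypertension
follows JNC 7.  The coded diagnosis in the record (ICPC T90 / K86 / K87) is
the "test" under validation; these engines compute the reference standard it
is judged against.

All thresholds are inclusive (``>=``) and live in :data:`CRITERIA_THRESHOLDS`
so reports can export them verbatim; no literal appears inside rule code.

Eligibility: a patient can only be validated for diabetes if at least one
plasma-glucose measurement exists, and for hypertension if blood pressure was
recorded on at least two office visits — except that the therapy-plus-history
criteria need no measurement at all, so patients satisfying those remain
eligible (and positive) without labs or readings.  No temporal window is
applied: every record in the bundle counts, whatever its date.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from statistics import fmean

from .records import Condition, DrugClass, GlucoseKind, PatientBundle

__all__ = [
    "CRITERIA_THRESHOLDS",
    "Status",
    "CriteriaResult",
    "BPVisitSummary",
    "dm_eligible",
    "htn_eligible",
    "classify_dm",
    "summarize_bp_visits",
    "classify_htn",
]

#: Every numeric threshold used by the rule engines, exported in reports.
CRITERIA_THRESHOLDS: dict[str, float] = {
    "dm_fasting_glucose_mgdl": 126.0,
    "dm_random_glucose_mgdl": 200.0,
    "dm_ogtt75_2h_mgdl": 200.0,
    "gdm_ogtt100_fasting_mgdl": 95.0,
    "gdm_ogtt100_1h_mgdl": 180.0,
    "gdm_ogtt100_2h_mgdl": 155.0,
    "gdm_ogtt100_3h_mgdl": 140.0,
    "gdm_min_values_met": 2,
    "htn_systolic_mmhg": 140.0,
    "htn_diastolic_mmhg": 90.0,
    "htn_systolic_high_risk_mmhg": 130.0,  # diabetes or chronic kidney disease
    "htn_diastolic_high_risk_mmhg": 80.0,
    "htn_min_visits": 2,
}

_GDM_POINTS = {
    GlucoseKind.OGTT100_FASTING: CRITERIA_THRESHOLDS["gdm_ogtt100_fasting_mgdl"],
    GlucoseKind.OGTT100_1H: CRITERIA_THRESHOLDS["gdm_ogtt100_1h_mgdl"],
    GlucoseKind.OGTT100_2H: CRITERIA_THRESHOLDS["gdm_ogtt100_2h_mgdl"],
    GlucoseKind.OGTT100_3H: CRITERIA_THRESHOLDS["gdm_ogtt100_3h_mgdl"],
}


class Status(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    INELIGIBLE = "ineligible"


@dataclass(slots=True)
class CriteriaResult:
    """Gold-standard classification plus which criteria fired.

    ``status`` is positive iff ``fired_criteria`` is non-empty; an ineligible
    result carries no fired criteria.
    """

    status: Status
    fired_criteria: list[str] = field(default_factory=list)
    supporting_values: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status is Status.POSITIVE) != bool(self.fired_criteria):
            raise ValueError("status=positive iff fired_criteria non-empty")
        if self.status is Status.INELIGIBLE and self.fired_criteria:
            raise ValueError("ineligible result cannot carry fired criteria")


@dataclass(frozen=True, slots=True)
class BPVisitSummary:
    visit_id: str
    n_readings: int
    mean_systolic: float
    mean_diastolic: float


def _dm_therapy_history(bundle: PatientBundle) -> Condition | None:
    """The history condition (DM or GDM) backing the therapy criterion, if any."""
    on_therapy = any(m.drug_class is DrugClass.ANTIDIABETIC for m in bundle.medications)
    if not on_therapy:
        return None
    conditions = {h.condition for h in bundle.history_notes}
    if Condition.DM in conditions:
        return Condition.DM
    if Condition.GDM in conditions:
        return Condition.GDM
    return None


def _htn_therapy_history(bundle: PatientBundle) -> bool:
    on_therapy = any(m.drug_class is DrugClass.ANTIHYPERTENSIVE for m in bundle.medications)
    return on_therapy and any(h.condition is Condition.HTN for h in bundle.history_notes)


def dm_eligible(bundle: PatientBundle) -> bool:
    """Whether the diabetes gold standard can be evaluated for this patient.

    Requires at least one plasma-glucose measurement of any kind, except that
    the therapy-plus-history criterion needs no lab and keeps the patient
    eligible on its own.
    """
    return bool(bundle.glucose) or _dm_therapy_history(bundle) is not None


def htn_eligible(bundle: PatientBundle) -> bool:
    """Whether the hypertension gold standard can be evaluated.

    Requires blood-pressure readings on at least two distinct office visits,
    or the antihypertensive-therapy-plus-history criterion.
    """
    visits = {r.visit_id for r in bundle.bp}
    return len(visits) >= CRITERIA_THRESHOLDS["htn_min_visits"] or _htn_therapy_history(bundle)


def classify_dm(bundle: PatientBundle) -> CriteriaResult:
    """Apply the diabetes reference criteria to one patient.

    Positive iff any of:

    a. any fasting plasma glucose >= 126 mg/dl;
    b. documented hyperglycemia symptoms and any random glucose >= 200 mg/dl;
    c. any 2-h value of a 75-g OGTT >= 200 mg/dl;
    d. on antidiabetic therapy with a prior DM diagnosis in the record;
    e. gestational DM: pregnant, with >= 2 of the four 100-g OGTT points
       (same test date) at or above 95/180/155/140 mg/dl;
    f. on antidiabetic therapy with a prior gestational-DM diagnosis.

    Returns an ineligible result when :func:`dm_eligible` is false.
    """
    if not dm_eligible(bundle):
        return CriteriaResult(Status.INELIGIBLE)

    fired: list[str] = []
    support: list[tuple[str, float]] = []

    for g in bundle.glucose:
        if g.kind is GlucoseKind.FASTING and g.value >= CRITERIA_THRESHOLDS["dm_fasting_glucose_mgdl"]:
            if "FPG>=126" not in fired:
                fired.append("FPG>=126")
            support.append((f"fasting@{g.date.isoformat()}", g.value))
        elif (
            g.kind is GlucoseKind.RANDOM
            and bundle.hyperglycemia_symptoms_flag
            and g.value >= CRITERIA_THRESHOLDS["dm_random_glucose_mgdl"]
        ):
            if "symptoms+random>=200" not in fired:
                fired.append("symptoms+random>=200")
            support.append((f"random@{g.date.isoformat()}", g.value))
        elif g.kind is GlucoseKind.OGTT75_2H and g.value >= CRITERIA_THRESHOLDS["dm_ogtt75_2h_mgdl"]:
            if "OGTT75_2h>=200" not in fired:
                fired.append("OGTT75_2h>=200")
            support.append((f"ogtt75_2h@{g.date.isoformat()}", g.value))

    therapy = _dm_therapy_history(bundle)
    if therapy is Condition.DM:
        fired.append("therapy+history")
    elif therapy is Condition.GDM:
        fired.append("GDM_therapy+history")

    if bundle.pregnant_flag:
        by_date: dict[object, int] = {}
        for g in bundle.glucose:
            threshold = _GDM_POINTS.get(g.kind)
            if threshold is not None and g.value >= threshold:
                by_date[g.date] = by_date.get(g.date, 0) + 1
        if any(n >= CRITERIA_THRESHOLDS["gdm_min_values_met"] for n in by_date.values()):
            fired.append("GDM_OGTT100")

    status = Status.POSITIVE if fired else Status.NEGATIVE
    return CriteriaResult(status, fired, support)


def summarize_bp_visits(bundle: PatientBundle) -> list[BPVisitSummary]:
    """Arithmetic per-visit means of the blood-pressure readings.

    One summary per distinct ``visit_id``, in order of first appearance.
    """
    order: list[str] = []
    groups: dict[str, list] = {}
    for r in bundle.bp:
        if r.visit_id not in groups:
            groups[r.visit_id] = []
            order.append(r.visit_id)
        groups[r.visit_id].append(r)
    return [
        BPVisitSummary(
            visit_id=vid,
            n_readings=len(groups[vid]),
            mean_systolic=fmean(r.systolic for r in groups[vid]),
            mean_diastolic=fmean(r.diastolic for r in groups[vid]),
        )
        for vid in order
    ]


def classify_htn(bundle: PatientBundle, dm_status: bool) -> CriteriaResult:
    """Apply the hypertension reference criteria to one patient.

    ``dm_status`` is the patient's (gold-standard) diabetes classification; it
    selects the 130/80 mmHg threshold pair together with the chronic-kidney-
    disease flag, otherwise 140/90 applies.  The office-BP criterion averages
    the per-visit means across all visits with at least one reading and
    requires at least two such visits.  The therapy-plus-history criterion
    needs no readings and by itself keeps the patient eligible.
    """
    high_risk = dm_status or bundle.ckd_flag
    if high_risk:
        th_sys = CRITERIA_THRESHOLDS["htn_systolic_high_risk_mmhg"]
        th_dia = CRITERIA_THRESHOLDS["htn_diastolic_high_risk_mmhg"]
    else:
        th_sys = CRITERIA_THRESHOLDS["htn_systolic_mmhg"]
        th_dia = CRITERIA_THRESHOLDS["htn_diastolic_mmhg"]

    therapy = _htn_therapy_history(bundle)
    if not htn_eligible(bundle) and not therapy:
        return CriteriaResult(Status.INELIGIBLE)

    fired: list[str] = []
    support: list[tuple[str, float]] = []

    visits = summarize_bp_visits(bundle)
    if len(visits) >= CRITERIA_THRESHOLDS["htn_min_visits"]:
        grand_sys = fmean(v.mean_systolic for v in visits)
        grand_dia = fmean(v.mean_diastolic for v in visits)
        if grand_sys >= th_sys:
            fired.append("SBP_mean>=threshold")
            support.append(("grand_mean_systolic", grand_sys))
        if grand_dia >= th_dia:
            fired.append("DBP_mean>=threshold")
            support.append(("grand_mean_diastolic", grand_dia))

    if therapy:
        fired.append("antihypertensive+history")

    status = Status.POSITIVE if fired else Status.NEGATIVE
    return CriteriaResult(status, fired, support)
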