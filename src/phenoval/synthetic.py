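"""Synthetic primary-care cohort generator with known latent disease status.

Every downstream stage (criteria engines, sampling, statistics) is testable
against this generator because the latent truth is known and, on patients
with complete measurements, the gold-standard engines classify exactly the
latent status: true diabetics receive fasting glucose drawn clear above the
126 mg/dl threshold (or a 100-g OGTT pattern for gestational cases), true
hypertensives receive per-visit blood-pressure means clear above the
applicable 140/90 or 130/80 mmHg pair, and unaffected patients' values stay
clear below.  Diagnosis codes are then assigned by independent Bernoulli
draws against the latent truth with configurable coding sensitivity and
specificity, and a configurable fraction of patients is stripped of glucose
records / left with fewer than two blood-pressure visits to emulate
real-world measurement missingness.

Age acts on disease risk through per-band relative risks, normalised so the
configured marginal prevalences hold in expectation; this reproduces the
strong age gradient of both diseases (roughly half of coded diabetics and
hypertensives are 70 or older) that the matched sampling design exercises.

Value distributions are conventions: the emulated study reports thresholds,
not population distributions, so uniform draws clear of the boundaries are
used.  Boundary behaviour is exercised by dedicated fixtures, not here.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    BPReading,
    Cohort,
    DM_CODES,
    Episode,
    GlucoseMeasurement,
    HistoryNote,
    HTN_CODES,
    MedicationRecord,
    PatientBundle,
    has_code,
)
from .stats import ConfusionTable

__all__ = [
    "AgeBand",
    "SyntheticConfig",
    "LatentTruth",
    "generate_cohort",
    "truth_confusion",
    "write_truth",
    "read_truth",
]

INDEX_DATE = _dt.date(2010, 1, 1)

_BACKGROUND_EPISODES = [("R05", "cough"), ("L03", "low back symptom"),
                        ("A97", "no disease"), ("D87", "stomach function disorder")]


@dataclass(frozen=True, slots=True)
class AgeBand:
    """One age band of the population mixture.

    ``weight`` is the population share; ``dm_rr`` / ``htn_rr`` are relative
    risks of latent disease for the band (normalised internally so the
    configured marginal prevalence is preserved).
    """

    low: int
    high: int
    weight: float
    dm_rr: float
    htn_rr: float


#: Default adult primary-care age mixture.  The >= 70 relative risks are set
#: so that about half of the coded diabetic and hypertensive patients are 70
#: or older, preserving the age-stratification structure under validation.
DEFAULT_AGE_BANDS: tuple[AgeBand, ...] = (
    AgeBand(18, 39, 0.40, 0.15, 0.15),
    AgeBand(40, 54, 0.25, 0.60, 0.70),
    AgeBand(55, 69, 0.20, 1.80, 2.20),
    AgeBand(70, 90, 0.15, 4.20, 5.50),
)


@dataclass(frozen=True, slots=True)
class LatentTruth:
    patient_id: str
    true_dm: bool
    true_gdm: bool
    true_htn: bool


@dataclass(frozen=True, slots=True)
class SyntheticConfig:
    """Generator parameters.

    The defaults emulate an adult primary-care population: latent diabetes
    prevalence 5%, latent hypertension around 16-17% overall (80% among
    diabetics), diabetes coding nearly complete (sensitivity 0.975,
    specificity 0.9997) and hypertension visibly under-coded (sensitivity
    0.82, specificity 0.998), with 7.3% of patients lacking any glucose
    determination and 22.9% lacking blood pressure on two visits.
    """

    n_patients: int = 20_000
    seed: int = 0
    dm_prevalence: float = 0.05
    htn_prevalence: float = 0.17
    htn_prevalence_given_dm: float = 0.80
    coding_sensitivity_dm: float = 0.975
    coding_specificity_dm: float = 0.9997
    coding_sensitivity_htn: float = 0.82
    coding_specificity_htn: float = 0.998
    p_missing_glucose: float = 0.073
    p_missing_bp_pair: float = 0.229
    female_fraction: float = 0.56
    gdm_fraction: float = 0.0  # fraction of true-DM women under 46 with the gestational pattern
    p_ckd: float = 0.03
    p_symptoms: float = 0.05
    p_therapy_records: float = 0.5  # chance a true case also carries therapy + history note
    glucose_noise_sd: float = 5.0  # mg/dl
    bp_noise_sd: float = 3.0  # mmHg within-visit reading jitter
    age_bands: tuple[AgeBand, ...] = DEFAULT_AGE_BANDS

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        proportions = {
            "dm_prevalence": self.dm_prevalence,
            "htn_prevalence": self.htn_prevalence,
            "htn_prevalence_given_dm": self.htn_prevalence_given_dm,
            "coding_sensitivity_dm": self.coding_sensitivity_dm,
            "coding_specificity_dm": self.coding_specificity_dm,
            "coding_sensitivity_htn": self.coding_sensitivity_htn,
            "coding_specificity_htn": self.coding_specificity_htn,
            "p_missing_glucose": self.p_missing_glucose,
            "p_missing_bp_pair": self.p_missing_bp_pair,
            "female_fraction": self.female_fraction,
            "gdm_fraction": self.gdm_fraction,
            "p_ckd": self.p_ckd,
            "p_symptoms": self.p_symptoms,
            "p_therapy_records": self.p_therapy_records,
        }
        for name, v in proportions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.age_bands:
            raise ValueError("age_bands must be non-empty")
        if abs(sum(b.weight for b in self.age_bands) - 1.0) > 1e-9:
            raise ValueError("age band weights must sum to 1")
        if self.glucose_noise_sd < 0 or self.bp_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bands"] = [asdict(b) for b in self.age_bands]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "age_bands" in d:
            d["age_bands"] = tuple(AgeBand(**b) for b in d["age_bands"])
        return cls(**d)


def _date_from_offset(offset: int) -> _dt.date:
    return INDEX_DATE - _dt.timedelta(days=int(offset))


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, list[LatentTruth]]:
    """Generate a cohort plus its latent truth table, deterministically per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    bands = config.age_bands

    weights = np.array([b.weight for b in bands])
    band_idx = rng.choice(len(bands), size=n, p=weights / weights.sum())
    lows = np.array([b.low for b in bands])
    highs = np.array([b.high for b in bands])
    ages = rng.integers(lows[band_idx], highs[band_idx] + 1)
    female = rng.random(n) < config.female_fraction

    # Latent disease: band relative risks normalised to keep the marginal
    # prevalence at its configured value.
    dm_rr = np.array([b.dm_rr for b in bands])
    htn_rr = np.array([b.htn_rr for b in bands])
    mean_dm_rr = float(weights @ dm_rr)
    mean_htn_rr = float(weights @ htn_rr)
    p_dm = np.clip(config.dm_prevalence * dm_rr[band_idx] / mean_dm_rr, 0.0, 1.0)
    true_dm = rng.random(n) < p_dm
    # non-diabetic base chosen so the overall margin stays near htn_prevalence
    base_nondm = config.htn_prevalence
    if config.dm_prevalence < 1.0:
        base_nondm = max(
            0.0,
            (config.htn_prevalence - config.dm_prevalence * config.htn_prevalence_given_dm)
            / (1.0 - config.dm_prevalence),
        )
    p_htn = np.where(
        true_dm,
        config.htn_prevalence_given_dm,
        np.clip(base_nondm * htn_rr[band_idx] / mean_htn_rr, 0.0, 1.0),
    )
    true_htn = rng.random(n) < p_htn

    gdm_eligible = true_dm & female & (ages <= 45)
    true_gdm = gdm_eligible & (rng.random(n) < config.gdm_fraction)

    ckd = rng.random(n) < config.p_ckd
    symptoms = rng.random(n) < np.where(true_dm, 0.3, config.p_symptoms)
    pregnant = true_gdm

    coded_dm = np.where(
        true_dm,
        rng.random(n) < config.coding_sensitivity_dm,
        rng.random(n) < 1.0 - config.coding_specificity_dm,
    )
    coded_htn = np.where(
        true_htn,
        rng.random(n) < config.coding_sensitivity_htn,
        rng.random(n) < 1.0 - config.coding_specificity_htn,
    )
    htn_code = np.where(rng.random(n) < 0.85, "K86", "K87")

    miss_glu = rng.random(n) < config.p_missing_glucose
    miss_bp = rng.random(n) < config.p_missing_bp_pair

    therapy_dm = true_dm & (rng.random(n) < config.p_therapy_records)
    therapy_htn = true_htn & (rng.random(n) < config.p_therapy_records)

    # Measurement values, drawn in bulk.  Ranges stay clear of the diagnostic
    # thresholds; the within-range noise is clipped so no draw crosses over.
    n_glu = rng.integers(1, 3, size=n)  # 1 or 2 fasting values
    glu_noise = rng.normal(0.0, config.glucose_noise_sd, size=(n, 2))
    fasting_dm = np.clip(rng.uniform(130.0, 250.0, size=(n, 2)) + glu_noise, 127.0, 1400.0)
    fasting_nondm = np.clip(rng.uniform(70.0, 118.0, size=(n, 2)) + glu_noise, 20.0, 124.0)
    random_high = np.clip(rng.uniform(210.0, 350.0, size=n), 201.0, 1400.0)
    random_low = np.clip(rng.uniform(80.0, 150.0, size=n), 20.0, 198.0)
    ogtt100 = np.column_stack([
        np.clip(rng.uniform(97.0, 115.0, size=n), 96.0, 200.0),   # fasting >= 95
        np.clip(rng.uniform(182.0, 220.0, size=n), 181.0, 400.0),  # 1 h >= 180
        np.clip(rng.uniform(120.0, 150.0, size=n), 50.0, 154.0),   # 2 h < 155
        np.clip(rng.uniform(100.0, 135.0, size=n), 50.0, 139.0),   # 3 h < 140
    ])

    high_risk = true_dm | ckd  # 130/80 threshold applies
    n_visits = rng.integers(2, 4, size=n)  # 2 or 3 visits when BP is complete
    sys_htn = np.where(
        high_risk[:, None], rng.uniform(134.0, 170.0, size=(n, 3)),
        rng.uniform(144.0, 180.0, size=(n, 3)),
    )
    dia_htn = np.where(
        high_risk[:, None], rng.uniform(84.0, 100.0, size=(n, 3)),
        rng.uniform(94.0, 110.0, size=(n, 3)),
    )
    sys_norm = np.where(
        high_risk[:, None], rng.uniform(100.0, 124.0, size=(n, 3)),
        rng.uniform(104.0, 134.0, size=(n, 3)),
    )
    dia_norm = np.where(
        high_risk[:, None], rng.uniform(62.0, 76.0, size=(n, 3)),
        rng.uniform(64.0, 84.0, size=(n, 3)),
    )
    sys_mean = np.where(true_htn[:, None], sys_htn, sys_norm)
    dia_mean = np.where(true_htn[:, None], dia_htn, dia_norm)
    # paired jitter keeps the per-visit mean exact (reading = mean +/- e)
    bp_jitter = np.clip(rng.normal(0.0, config.bp_noise_sd, size=(n, 3)), -8.0, 8.0)

    offsets = rng.integers(30, 1000, size=(n, 12))
    bg_episode = rng.random(n) < 0.25
    bg_choice = rng.integers(0, len(_BACKGROUND_EPISODES), size=n)
    other_med = rng.random(n) < 0.2

    width = len(str(n))
    patients: list[PatientBundle] = []
    truths: list[LatentTruth] = []
    for i in range(n):
        pid = f"p{i:0{width}d}"
        b = PatientBundle(
            patient_id=pid,
            sex="female" if female[i] else "male",
            age=int(ages[i]),
            ckd_flag=bool(ckd[i]),
            pregnant_flag=bool(pregnant[i]),
            hyperglycemia_symptoms_flag=bool(symptoms[i]),
        )

        if coded_dm[i]:
            b.episodes.append(Episode("T90", "diabetes mellitus", _date_from_offset(offsets[i, 0])))
        if coded_htn[i]:
            b.episodes.append(
                Episode(str(htn_code[i]), "hypertension", _date_from_offset(offsets[i, 1]))
            )
        if bg_episode[i]:
            code, label = _BACKGROUND_EPISODES[bg_choice[i]]
            b.episodes.append(Episode(code, label, _date_from_offset(offsets[i, 2])))

        if not miss_glu[i]:
            if true_gdm[i]:
                test_date = _date_from_offset(offsets[i, 3])
                for kind, value in zip(
                    ("ogtt100_fasting", "ogtt100_1h", "ogtt100_2h", "ogtt100_3h"), ogtt100[i]
                ):
                    b.glucose.append(GlucoseMeasurement(test_date, kind, float(value)))
            else:
                values = fasting_dm[i] if true_dm[i] else fasting_nondm[i]
                for k in range(int(n_glu[i])):
                    b.glucose.append(
                        GlucoseMeasurement(_date_from_offset(offsets[i, 3 + k]), "fasting",
                                           float(values[k]))
                    )
                if symptoms[i]:
                    value = random_high[i] if true_dm[i] else random_low[i]
                    b.glucose.append(
                        GlucoseMeasurement(_date_from_offset(offsets[i, 5]), "random", float(value))
                    )

        n_vis = 1 if miss_bp[i] else int(n_visits[i])
        n_readings = 1 if miss_bp[i] else 2
        for v in range(n_vis):
            date = _date_from_offset(offsets[i, 6 + v])
            for sign in ((0.0,) if n_readings == 1 else (1.0, -1.0)):
                b.bp.append(
                    BPReading(
                        visit_id=f"{pid}-v{v}",
                        date=date,
                        systolic=float(sys_mean[i, v] + sign * bp_jitter[i, v]),
                        diastolic=float(dia_mean[i, v] + sign * bp_jitter[i, v]),
                    )
                )

        if therapy_dm[i]:
            b.medications.append(
                MedicationRecord(_date_from_offset(offsets[i, 9]), "antidiabetic")
            )
            b.history_notes.append(
                HistoryNote("GDM" if true_gdm[i] else "DM", _date_from_offset(offsets[i, 9]))
            )
        if therapy_htn[i]:
            b.medications.append(
                MedicationRecord(_date_from_offset(offsets[i, 10]), "antihypertensive")
            )
            b.history_notes.append(HistoryNote("HTN", _date_from_offset(offsets[i, 10])))
        if other_med[i]:
            b.medications.append(MedicationRecord(_date_from_offset(offsets[i, 11]), "other"))

        patients.append(b)
        truths.append(
            LatentTruth(pid, bool(true_dm[i]), bool(true_gdm[i]), bool(true_htn[i]))
        )

    cohort = Cohort(patients, provenance=f"synthetic(seed={config.seed}, n={n})")
    return cohort, truths


def truth_confusion(
    cohort: Cohort, truth: Sequence[LatentTruth], disease: str
) -> ConfusionTable:
    """Cross-tabulate coded status against latent truth over the whole cohort.

    The oracle for coding-parameter recovery: with perfect coding the
    off-diagonal cells are zero, and at large n the cell ratios converge to
    the configured coding sensitivity/specificity.
    """
    disease = disease.upper()
    if disease == "DM":
        codes, attr = DM_CODES, "true_dm"
    elif disease == "HTN":
        codes, attr = HTN_CODES, "true_htn"
    else:
        raise ValueError(f"disease must be 'DM' or 'HTN', got {disease!r}")
    by_id = {t.patient_id: t for t in truth}
    tp = fp = fn = tn = 0
    for b in cohort:
        if b.patient_id not in by_id:
            raise KeyError(f"missing truth record for patient {b.patient_id!r}")
        coded = has_code(b, codes)
        positive = getattr(by_id[b.patient_id], attr)
        if coded and positive:
            tp += 1
        elif coded:
            fp += 1
        elif positive:
            fn += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)


def write_truth(truth: Sequence[LatentTruth], path) -> None:
    """Write the latent truth table as truth.csv."""
    df = pd.DataFrame(
        [(t.patient_id, str(t.true_dm).lower(), str(t.true_gdm).lower(),
          str(t.true_htn).lower()) for t in truth],
        columns=["patient_id", "true_dm", "true_gdm", "true_htn"],
    )
    df.to_csv(Path(path), index=False)


def read_truth(path) -> list[LatentTruth]:
    df = pd.read_csv(Path(path), dtype=str)
    return [
        LatentTruth(r.patient_id, r.true_dm == "true", r.true_gdm == "true",
                    r.true_htn == "true")
        for r in df.itertuples(index=False)
    ]
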