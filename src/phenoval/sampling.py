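"""Validation-sample construction: size, random draw, individual matching,
and measurement-availability exclusions.

The design validates a coded diagnosis with two arms per disease: a simple
random sample of code-positive patients, and an uncoded arm built by
individual age/sex matching to the coded arm.  Sample size comes from the
binomial precision formula under maximum indetermination (p = 0.5), inflated
for anticipated losses.  Patients without the measurements needed to evaluate
the gold standard are excluded after matching (pairs are not replaced), so
frames only ever shrink.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import stats as sps

from .criteria import dm_eligible, htn_eligible
from .records import Cohort, PatientBundle, has_code

__all__ = [
    "SamplingSpec",
    "SampleFrame",
    "required_sample_size",
    "draw_coded_sample",
    "draw_matched_sample",
    "apply_measurement_exclusions",
    "InsufficientPopulationError",
]

logger = logging.getLogger(__name__)

ADULT_AGE = 18


class InsufficientPopulationError(RuntimeError):
    """Not enough eligible patients to draw the requested sample."""


@dataclass(frozen=True, slots=True)
class SamplingSpec:
    disease: Literal["DM", "HTN"]
    code_set: frozenset[str]
    n_target: int = 423
    seed: int = 0
    sex_exact: bool = True
    age_tolerance: int = 2

    def __post_init__(self) -> None:
        if self.n_target < 1:
            raise ValueError("n_target must be >= 1")
        if self.age_tolerance < 0:
            raise ValueError("age_tolerance must be >= 0")
        object.__setattr__(self, "code_set", frozenset(self.code_set))


@dataclass(slots=True)
class SampleFrame:
    members: list[str]
    arm: Literal["coded", "uncoded"]
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate members in sample frame")
        excluded_ids = {pid for pid, _ in self.excluded}
        if excluded_ids & set(self.members):
            raise ValueError("members and excluded ids overlap")


def required_sample_size(
    p: float, precision: float, confidence: float = 0.95, loss_fraction: float = 0.0
) -> int:
    """Binomial sample size n = z^2 p(1-p)/d^2, inflated for anticipated losses.

    The base size is rounded to the nearest integer (the convention of the
    emulated design: p = 0.5, d = 0.05, 95% confidence gives exactly 384);
    the loss inflation is ceil(n * (1 + loss_fraction)) (10% loss gives 423).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    if precision <= 0.0:
        raise ValueError(f"precision must be > 0, got {precision}")
    if not 0.0 < confidence < 1.0:
        raise ValueError(f"confidence must be in (0, 1), got {confidence}")
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError(f"loss_fraction must be in [0, 1), got {loss_fraction}")
    z = float(sps.norm.ppf(0.5 + confidence / 2.0))
    n0 = z * z * p * (1.0 - p) / (precision * precision)
    n = math.floor(n0 + 0.5)  # half-up, immune to banker's rounding
    return math.ceil(n * (1.0 + loss_fraction) - 1e-9)


def _adults(cohort: Cohort) -> list[PatientBundle]:
    return [b for b in cohort if b.age >= ADULT_AGE]


def draw_coded_sample(cohort: Cohort, spec: SamplingSpec) -> SampleFrame:
    """Simple random sample, without replacement, of code-positive adults."""
    eligible = [b.patient_id for b in _adults(cohort) if has_code(b, spec.code_set)]
    if len(eligible) < spec.n_target:
        raise InsufficientPopulationError(
            f"need {spec.n_target} coded patients, only {len(eligible)} available"
        )
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(len(eligible), size=spec.n_target, replace=False)
    return SampleFrame(members=[eligible[i] for i in idx], arm="coded")


def draw_matched_sample(
    cohort: Cohort, reference: SampleFrame, spec: SamplingSpec
) -> SampleFrame:
    """Uncoded arm individually matched to the reference by sex and age.

    For each reference member one uncoded adult of identical sex (when
    ``sex_exact``) within ``age_tolerance`` years is drawn uniformly among the
    remaining candidates, without replacement across matches.  A reference
    member with no remaining candidate is recorded as unmatched (the pair is
    dropped) with a logged warning.
    """
    rng = np.random.default_rng(spec.seed + 1)
    # candidate pools keyed by (sex, age)
    pools: dict[tuple[str, int], list[str]] = {}
    for b in _adults(cohort):
        if not has_code(b, spec.code_set):
            pools.setdefault((b.sex.value, b.age), []).append(b.patient_id)

    members: list[str] = []
    excluded: list[tuple[str, str]] = []
    used: set[str] = set()
    for pid in reference.members:
        ref = cohort.get(pid)
        sexes = [ref.sex.value] if spec.sex_exact else ["male", "female"]
        candidates: list[str] = []
        for sex in sexes:
            for age in range(ref.age - spec.age_tolerance, ref.age + spec.age_tolerance + 1):
                candidates.extend(c for c in pools.get((sex, age), ()) if c not in used)
        if not candidates:
            logger.warning("no match for reference member %s (%s, age %d); pair dropped",
                           pid, ref.sex.value, ref.age)
            excluded.append((pid, "unmatched_reference"))
            continue
        chosen = candidates[int(rng.integers(len(candidates)))]
        used.add(chosen)
        members.append(chosen)
    return SampleFrame(members=members, arm="uncoded", excluded=excluded)


def apply_measurement_exclusions(
    frame: SampleFrame, cohort: Cohort, disease: Literal["DM", "HTN"]
) -> SampleFrame:
    """Remove members whose records cannot support the gold standard.

    Diabetes validation needs at least one plasma glucose ("no_glucose");
    hypertension validation needs blood pressure on two visits
    ("insufficient_bp").  The therapy-plus-history criteria keep a patient
    eligible without measurements.  Reasons partition the removed set; the
    frame only shrinks.
    """
    disease = disease.upper()
    if disease == "DM":
        check, reason = dm_eligible, "no_glucose"
    elif disease == "HTN":
        check, reason = htn_eligible, "insufficient_bp"
    else:
        raise ValueError(f"disease must be 'DM' or 'HTN', got {disease!r}")
    kept: list[str] = []
    excluded = list(frame.excluded)
    for pid in frame.members:
        if check(cohort.get(pid)):
            kept.append(pid)
        else:
            excluded.append((pid, reason))
    return SampleFrame(members=kept, arm=frame.arm, excluded=excluded)
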