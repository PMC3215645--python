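"""End-to-end orchestration: generate (or load) -> classify -> sample ->
validate -> report, as one reproducible run.

A single root seed deterministically derives the per-stage seeds, so one
integer reproduces an entire run byte-for-byte.  Reports carry the criteria
thresholds and the CI/test method names so every number is auditable.

:func:`replay_from_counts` runs the statistics chain alone on externally
supplied 2x2 counts, which is how published validation tables can be
re-derived without any patient-level data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from . import __version__ as _version
from .criteria import (
    CRITERIA_THRESHOLDS,
    CriteriaResult,
    Status,
    classify_dm,
    classify_htn,
    dm_eligible,
    htn_eligible,
)
from .io import read_cohort, write_cohort
from .records import Cohort, DM_CODES, HTN_CODES, PatientBundle, has_code
from .sampling import (
    SampleFrame,
    SamplingSpec,
    apply_measurement_exclusions,
    draw_coded_sample,
    draw_matched_sample,
)
from .stats import (
    ClassifiedSubject,
    ConfusionTable,
    ProportionEstimate,
    StratumCounts,
    ValidationReport,
    cohen_kappa,
    design_corrected_accuracy,
    npv_direct,
    ppv_direct,
    predictive_value_intervals,
    predictive_values_at_prevalence,
    prevalence_grid,
    rogan_gladen,
    sensitivity,
    specificity,
    stratified_validation,
)
from .synthetic import SyntheticConfig, generate_cohort, write_truth

__all__ = ["RunConfig", "RunResult", "run_validation", "replay_from_counts",
           "classify_arms", "coding_recovery_replicate", "coding_recovery_study",
           "DEFAULT_PREVALENCE_GRID"]

logger = logging.getLogger(__name__)

#: The prevalence grid of the sensitivity analysis (4%..15% in fine steps,
#: then 20%..50%).
DEFAULT_PREVALENCE_GRID: tuple[float, ...] = tuple(
    [x / 1000 for x in range(40, 100, 5)] + [x / 100 for x in range(10, 16)]
    + [x / 100 for x in range(20, 51, 5)]
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full validation run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    extract_dir: str | None = None  # read an existing extract instead of generating
    n_target: int = 423
    age_tolerance: int = 2
    sex_exact: bool = True
    confidence: float = 0.95
    prevalence_grid: tuple[float, ...] = DEFAULT_PREVALENCE_GRID
    age_cut: int = 70
    htn_dm_source: Literal["criteria", "code"] = "criteria"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must be in (0, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.prevalence_grid):
            raise ValueError("prevalence grid values must be in [0, 1]")
        if self.htn_dm_source not in ("criteria", "code"):
            raise ValueError("htn_dm_source must be 'criteria' or 'code'")
        self.synthetic.validate()

    def stage_seeds(self) -> dict[str, int]:
        """Per-stage seeds derived deterministically from the root seed."""
        ss = np.random.SeedSequence(self.seed)
        names = ("generate", "sample_dm", "sample_htn")
        children = ss.spawn(len(names))
        return {
            name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
            for name, child in zip(names, children)
        }


@dataclass
class RunResult:
    reports: dict[str, ValidationReport]
    sampling_report: dict
    seeds: dict[str, int]
    cohort: Cohort
    config: RunConfig


def _gold_dm(bundle: PatientBundle) -> bool:
    return classify_dm(bundle).status is Status.POSITIVE


def classify_arms(
    cohort: Cohort,
    coded: SampleFrame,
    uncoded: SampleFrame,
    disease: Literal["DM", "HTN"],
    htn_dm_source: Literal["criteria", "code"] = "criteria",
) -> list[ClassifiedSubject]:
    """Apply the gold-standard engine to both arms, attaching stratifiers.

    For hypertension, the diabetes status used both for the 130/80 threshold
    and for stratification comes from the gold-standard diabetes criteria by
    default, or from the T90 code when ``htn_dm_source='code'``.
    """
    subjects: list[ClassifiedSubject] = []
    for frame in (coded, uncoded):
        for pid in frame.members:
            b = cohort.get(pid)
            if disease == "DM":
                dm = _gold_dm(b)
                result = classify_dm(b)
            else:
                dm = has_code(b, DM_CODES) if htn_dm_source == "code" else _gold_dm(b)
                result = classify_htn(b, dm_status=dm)
            subjects.append(
                ClassifiedSubject(
                    patient_id=pid, arm=frame.arm, status=result.status,
                    sex=b.sex.value, age=b.age, dm=dm,
                )
            )
    return subjects


def _apparent_prevalence(cohort: Cohort, code_set) -> float:
    adults = [b for b in cohort if b.age >= 18]
    return sum(has_code(b, code_set) for b in adults) / len(adults)


def _validate_disease(
    cohort: Cohort, disease: Literal["DM", "HTN"], config: RunConfig, seed: int
) -> tuple[ValidationReport, dict]:
    code_set = DM_CODES if disease == "DM" else HTN_CODES
    spec = SamplingSpec(
        disease=disease, code_set=code_set, n_target=config.n_target,
        seed=seed, sex_exact=config.sex_exact, age_tolerance=config.age_tolerance,
    )
    coded = draw_coded_sample(cohort, spec)
    matched = draw_matched_sample(cohort, coded, spec)
    coded = apply_measurement_exclusions(coded, cohort, disease)
    matched = apply_measurement_exclusions(matched, cohort, disease)

    subjects = classify_arms(cohort, coded, matched, disease, config.htn_dm_source)
    report = stratified_validation(
        subjects, disease=disease, age_cut=config.age_cut, confidence=config.confidence
    )

    overall = report.strata["overall"]
    if overall.sensitivity is not None and overall.specificity is not None:
        apparent = _apparent_prevalence(cohort, code_set)
        report.prevalence_adjustment = rogan_gladen(
            apparent, overall.sensitivity.estimate, overall.specificity.estimate
        )
        report.grid = prevalence_grid(
            overall.sensitivity.estimate, overall.specificity.estimate,
            config.prevalence_grid,
        )
        adj = report.prevalence_adjustment.true_prevalence
        (ppv, ppv_lo, ppv_hi), (npv, npv_lo, npv_hi) = predictive_value_intervals(
            overall.sensitivity, overall.specificity, adj, config.confidence
        )
        report.extras["predictive_values_at_adjusted_prevalence"] = {
            "prevalence": adj,
            "ppv": ppv, "ppv_ci": [ppv_lo, ppv_hi],
            "npv": npv, "npv_ci": [npv_lo, npv_hi],
            "ci_method": "logit delta method over Wilson variances (approximate)",
        }
    report.extras["criteria_thresholds"] = dict(CRITERIA_THRESHOLDS)

    def _tally(frame: SampleFrame) -> dict:
        reasons: dict[str, int] = {}
        for _, reason in frame.excluded:
            reasons[reason] = reasons.get(reason, 0) + 1
        return {"n_members": len(frame.members), "exclusions": reasons}

    sampling_report = {
        "disease": disease,
        "seed": seed,
        "n_target": config.n_target,
        "matching": {"sex_exact": config.sex_exact, "age_tolerance": config.age_tolerance},
        "coded": _tally(coded),
        "uncoded": _tally(matched),
    }
    return report, sampling_report


def run_validation(config: RunConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute the full pipeline for both diseases.

    Deterministic: identical config (including seeds) produces identical
    reports.  When ``out_dir`` is given, writes ``sampling_report.json``,
    ``validation_dm.json`` / ``validation_htn.json``, the prevalence grids and
    the resolved configuration with all derived seeds.
    """
    config.validate()
    seeds = config.stage_seeds()

    if config.extract_dir is not None:
        logger.info("reading extract from %s", config.extract_dir)
        cohort = read_cohort(config.extract_dir)
    else:
        logger.info("generating synthetic cohort (seed %d)", seeds["generate"])
        cohort, _truth = generate_cohort(replace(config.synthetic, seed=seeds["generate"]))

    reports: dict[str, ValidationReport] = {}
    sampling: dict[str, dict] = {}
    for disease, seed_key in (("DM", "sample_dm"), ("HTN", "sample_htn")):
        try:
            reports[disease], sampling[disease] = _validate_disease(
                cohort, disease, config, seeds[seed_key]
            )
        except Exception as exc:
            raise RuntimeError(f"validation stage failed for {disease}: {exc}") from exc

    result = RunResult(
        reports=reports,
        sampling_report={"seeds": seeds, "per_disease": sampling},
        seeds=seeds,
        cohort=cohort,
        config=config,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_outputs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "sampling_report.json").write_text(
        json.dumps(result.sampling_report, indent=2, default=_json_default)
    )
    cfg = dataclasses.asdict(result.config)
    cfg["synthetic"] = result.config.synthetic.to_dict()
    cfg["derived_seeds"] = result.seeds
    cfg["package_version"] = _version
    (out_dir / "run_config.json").write_text(json.dumps(cfg, indent=2, default=_json_default))
    for disease, report in result.reports.items():
        (out_dir / f"validation_{disease.lower()}.json").write_text(
            json.dumps(report.to_dict(), indent=2, default=_json_default)
        )
        if report.grid is not None:
            report.grid.to_csv(out_dir / f"prevalence_grid_{disease.lower()}.csv", index=False)


def replay_from_counts(
    tp: int,
    fp: int,
    fn: int,
    tn: int,
    apparent_prevalence: float | None = None,
    prevalence_grid_values: Sequence[float] | None = None,
    confidence: float = 0.95,
) -> dict:
    """Statistics-only run from a published 2x2 table (no patient data).

    Returns sensitivity/specificity/direct predictive values with Wilson CIs,
    Cohen's kappa with CI and agreement label and, when an apparent prevalence
    is supplied, the Rogan-Gladen adjustment plus Bayes predictive values over
    the requested prevalence grid.
    """
    ct = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
    if ct.n == 0:
        raise ValueError("all-zero confusion table")
    out: dict = {"counts": {"tp": tp, "fp": fp, "fn": fn, "tn": tn}}
    sn = sensitivity(ct, confidence)
    sp = specificity(ct, confidence)
    kap = cohen_kappa(ct, confidence)
    out["sensitivity"] = sn
    out["specificity"] = sp
    out["ppv_direct"] = ppv_direct(ct, confidence)
    out["npv_direct"] = npv_direct(ct, confidence)
    out["kappa"] = kap
    if apparent_prevalence is not None:
        out["prevalence_adjustment"] = rogan_gladen(
            apparent_prevalence, sn.estimate, sp.estimate
        )
    if prevalence_grid_values:
        out["prevalence_grid"] = prevalence_grid(sn.estimate, sp.estimate,
                                                 prevalence_grid_values)
    out["methods"] = {
        "proportion_ci": "wilson (no continuity correction)",
        "kappa_ci": "Fleiss-Cohen-Everitt asymptotic SE",
        "criteria_thresholds": dict(CRITERIA_THRESHOLDS),
    }
    return out


# ---------------------------------------------------------------------------
# Coding-parameter recovery
# ---------------------------------------------------------------------------


def coding_recovery_replicate(
    config: SyntheticConfig,
    disease: Literal["DM", "HTN"],
    n_target: int = 423,
    seed: int = 0,
    age_tolerance: int = 2,
    cohort: Cohort | None = None,
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """One replicate of the coding-accuracy recovery study.

    Generates a cohort (unless one is supplied), draws the paired validation
    samples (random coded arm plus age/sex-matched uncoded arm of the same
    target size), classifies them with the gold-standard engines and feeds
    the per-age-band counts to
    :func:`phenoval.stats.design_corrected_accuracy`.  Returns the corrected
    (sensitivity, specificity) estimates with their conservative intervals,
    which should cover the configured coding parameters at (at least) the
    nominal rate.
    """
    if cohort is None:
        cohort, _ = generate_cohort(replace(config, seed=seed))
    code_set = DM_CODES if disease == "DM" else HTN_CODES
    spec = SamplingSpec(disease=disease, code_set=code_set, n_target=n_target,
                        seed=seed, age_tolerance=age_tolerance)
    coded = draw_coded_sample(cohort, spec)
    matched = draw_matched_sample(cohort, coded, spec)
    coded = apply_measurement_exclusions(coded, cohort, disease)
    matched = apply_measurement_exclusions(matched, cohort, disease)
    subjects = classify_arms(cohort, coded, matched, disease)

    bands = config.age_bands
    def band_of(age: int) -> int:
        for k, b in enumerate(bands):
            if b.low <= age <= b.high:
                return k
        return len(bands) - 1

    # Population stratum counts are restricted to gold-standard-eligible
    # patients: the sampled positivity refers to the eligible subpopulation
    # (therapy-backed cases stay eligible under missingness, so eligibility is
    # informative about the gold standard, while coding given truth is not).
    eligible = dm_eligible if disease == "DM" else htn_eligible
    n_coded = [0] * len(bands)
    n_uncoded = [0] * len(bands)
    for b in cohort:
        if b.age < 18 or not eligible(b):
            continue
        k = band_of(b.age)
        if has_code(b, code_set):
            n_coded[k] += 1
        else:
            n_uncoded[k] += 1

    sc = [0] * len(bands)
    pc = [0] * len(bands)
    su = [0] * len(bands)
    pu = [0] * len(bands)
    for s in subjects:
        if s.status is Status.INELIGIBLE:
            continue
        k = band_of(s.age)
        positive = s.status is Status.POSITIVE
        if s.arm == "coded":
            sc[k] += 1
            pc[k] += positive
        else:
            su[k] += 1
            pu[k] += positive

    strata = [
        StratumCounts(
            label=f"{bands[k].low}-{bands[k].high}",
            n_coded=n_coded[k], n_uncoded=n_uncoded[k],
            sampled_coded=sc[k], positive_coded=pc[k],
            sampled_uncoded=su[k], positive_uncoded=pu[k],
        )
        for k in range(len(bands))
    ]
    return design_corrected_accuracy(strata)


def coding_recovery_study(
    config: SyntheticConfig,
    n_replicates: int = 100,
    base_seed: int = 0,
    n_target: int = 423,
) -> dict[str, dict]:
    """Seeded replication study of coding-parameter recovery.

    For each replicate seed one cohort is generated and the full sampling +
    classification + design-corrected estimation chain is run for both
    diseases.  Returns, per parameter (``DM_sn``, ``DM_sp``, ``HTN_sn``,
    ``HTN_sp``), the configured value, the mean estimate, and the fraction of
    replicates whose interval covered the configured value.
    """
    targets = {
        "DM_sn": config.coding_sensitivity_dm,
        "DM_sp": config.coding_specificity_dm,
        "HTN_sn": config.coding_sensitivity_htn,
        "HTN_sp": config.coding_specificity_htn,
    }
    covered = {k: 0 for k in targets}
    sums = {k: 0.0 for k in targets}
    for r in range(n_replicates):
        seed = base_seed + r
        cohort, _ = generate_cohort(replace(config, seed=seed))
        for disease in ("DM", "HTN"):
            sn, sp = coding_recovery_replicate(
                config, disease, n_target=n_target, seed=seed, cohort=cohort
            )
            for key, est in ((f"{disease}_sn", sn), (f"{disease}_sp", sp)):
                covered[key] += est.ci_low <= targets[key] <= est.ci_high
                sums[key] += est.estimate
    return {
        key: {
            "configured": targets[key],
            "mean_estimate": sums[key] / n_replicates,
            "coverage": covered[key] / n_replicates,
        }
        for key in targets
    }
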