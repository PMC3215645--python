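"""Diagnostic-accuracy statistics.

Implements the full statistical chain for validating a coded diagnosis
against a gold standard: 2x2 confusion construction, sensitivity /
specificity / predictive values with Wilson score intervals, Cohen's kappa
with its asymptotic confidence interval and Landis-Koch label, chi-square /
Fisher homogeneity tests across strata, the Rogan-Gladen true-prevalence
adjustment, and Bayes predictive values across a prevalence grid.

Method pinning
--------------
* Proportion CIs: Wilson score without continuity correction.
* Kappa CI: the Fleiss-Cohen-Everitt large-sample standard error with
  z = Phi^{-1}(0.975) = 1.959964, truncated to [-1, 1].
* Homogeneity: Pearson chi-square without continuity correction when every
  expected cell count is >= 5, else the two-sided Fisher exact test.
* No multiple-testing correction: stratified p-values are reported raw.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .criteria import CriteriaResult, Status

__all__ = [
    "ConfusionTable",
    "ProportionEstimate",
    "KappaEstimate",
    "HomogeneityResult",
    "PrevalenceAdjustment",
    "UndefinedStatisticError",
    "build_confusion",
    "wilson_interval",
    "sensitivity",
    "specificity",
    "ppv_direct",
    "npv_direct",
    "cohen_kappa",
    "landis_koch_label",
    "homogeneity_test",
    "rogan_gladen",
    "predictive_values_at_prevalence",
    "predictive_value_intervals",
    "prevalence_grid",
    "ClassifiedSubject",
    "StratumResult",
    "ValidationReport",
    "stratified_validation",
    "StratumCounts",
    "design_corrected_accuracy",
]

_Z95 = float(sps.norm.ppf(0.975))


class UndefinedStatisticError(ZeroDivisionError):
    """A statistic is undefined for the given table (zero denominator etc.)."""


@dataclass(frozen=True, slots=True)
class ConfusionTable:
    """2x2 counts linking coded status (test) to gold-standard status.

    ``tp``: coded and criteria-positive; ``fp``: coded, criteria-negative;
    ``fn``: uncoded, criteria-positive; ``tn``: uncoded, criteria-negative.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionTable":
        """Swap the roles of test and gold standard (fp <-> fn)."""
        return ConfusionTable(tp=self.tp, fp=self.fn, fn=self.fp, tn=self.tn)


@dataclass(frozen=True, slots=True)
class ProportionEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n: int
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.estimate <= self.ci_high <= 1.0):
            raise ValueError(
                f"interval ordering violated: {self.ci_low}, {self.estimate}, {self.ci_high}"
            )

    def as_percent(self, digits: int = 2) -> tuple[float, float, float]:
        return tuple(round(100 * v, digits) for v in (self.estimate, self.ci_low, self.ci_high))


@dataclass(frozen=True, slots=True)
class KappaEstimate:
    kappa: float
    ci_low: float
    ci_high: float
    po: float
    pe: float
    label: str


@dataclass(frozen=True, slots=True)
class HomogeneityResult:
    statistic: float | None
    p_value: float
    method: Literal["pearson_chi2", "fisher_exact"]
    stratum_labels: tuple[str, str] = ("a", "b")


@dataclass(frozen=True, slots=True)
class PrevalenceAdjustment:
    apparent: float
    sn: float
    sp: float
    true_prevalence: float
    under_registration_pct: float | None


def build_confusion(
    coded_results: Sequence[CriteriaResult], uncoded_results: Sequence[CriteriaResult]
) -> ConfusionTable:
    """Cross-tabulate the two classified arms into a confusion table.

    The coded arm supplies TP (criteria-positive) and FP; the uncoded arm
    supplies FN (criteria-positive) and TN.  Ineligible results must already
    have been excluded upstream.
    """
    for r in list(coded_results) + list(uncoded_results):
        if r.status is Status.INELIGIBLE:
            raise ValueError("ineligible results must be removed before building a confusion table")
    tp = sum(r.status is Status.POSITIVE for r in coded_results)
    fn = sum(r.status is Status.POSITIVE for r in uncoded_results)
    return ConfusionTable(
        tp=tp, fp=len(coded_results) - tp, fn=fn, tn=len(uncoded_results) - fn
    )


def wilson_interval(successes: int, trials: int, confidence: float = 0.95) -> ProportionEstimate:
    """Wilson score interval (no continuity correction) for a binomial proportion."""
    if trials < 1:
        raise UndefinedStatisticError("Wilson interval needs at least one trial")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - confidence, method="wilson")
    estimate = successes / trials
    return ProportionEstimate(
        estimate=estimate,
        ci_low=min(max(float(lo), 0.0), estimate),
        ci_high=max(min(float(hi), 1.0), estimate),
        n=trials,
    )


def _ratio(name: str, num: int, den: int, confidence: float) -> ProportionEstimate:
    if den == 0:
        raise UndefinedStatisticError(f"{name} undefined: zero denominator")
    return wilson_interval(num, den, confidence)


def sensitivity(ct: ConfusionTable, confidence: float = 0.95) -> ProportionEstimate:
    """tp / (tp + fn): proportion of criteria-positive patients carrying the code."""
    return _ratio("sensitivity", ct.tp, ct.tp + ct.fn, confidence)


def specificity(ct: ConfusionTable, confidence: float = 0.95) -> ProportionEstimate:
    """tn / (tn + fp): proportion of criteria-negative patients without the code."""
    return _ratio("specificity", ct.tn, ct.tn + ct.fp, confidence)


def ppv_direct(ct: ConfusionTable, confidence: float = 0.95) -> ProportionEstimate:
    """tp / (tp + fp): criteria-positive fraction of the coded arm.

    Only interpretable as a predictive value when the table's column mix
    reflects the target population's prevalence; under code-based sampling use
    :func:`predictive_values_at_prevalence` instead.
    """
    return _ratio("ppv", ct.tp, ct.tp + ct.fp, confidence)


def npv_direct(ct: ConfusionTable, confidence: float = 0.95) -> ProportionEstimate:
    """tn / (tn + fn): criteria-negative fraction of the uncoded arm."""
    return _ratio("npv", ct.tn, ct.tn + ct.fn, confidence)


def landis_koch_label(kappa: float) -> str:
    """Agreement band for a kappa value: slight, fair, moderate, substantial,
    or almost perfect."""
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


def cohen_kappa(ct: ConfusionTable, confidence: float = 0.95) -> KappaEstimate:
    """Cohen's kappa for code-vs-criteria agreement, with asymptotic CI.

    po is the observed agreement (tp+tn)/n; pe the chance agreement from the
    margins.  The standard error is the Fleiss-Cohen-Everitt large-sample
    form; the interval is truncated to [-1, 1].
    """
    n = ct.n
    if n < 1:
        raise UndefinedStatisticError("kappa needs a non-empty table")
    p = np.array([[ct.tp, ct.fp], [ct.fn, ct.tn]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        raise UndefinedStatisticError("kappa undefined: degenerate margins (pe = 1)")
    kappa = (po - pe) / (1.0 - pe)

    a = sum(p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2))
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    se = math.sqrt(max(a + b - c, 0.0) / n) / (1.0 - pe)
    z = float(sps.norm.ppf(0.5 + confidence / 2))
    return KappaEstimate(
        kappa=kappa,
        ci_low=max(-1.0, kappa - z * se),
        ci_high=min(1.0, kappa + z * se),
        po=po,
        pe=pe,
        label=landis_koch_label(kappa),
    )


def _margin_counts(ct: ConfusionTable, margin: str) -> tuple[int, int]:
    if margin == "sensitivity":
        return ct.tp, ct.fn
    if margin == "specificity":
        return ct.tn, ct.fp
    raise ValueError(f"margin must be 'sensitivity' or 'specificity', got {margin!r}")


def homogeneity_test(
    ct_a: ConfusionTable,
    ct_b: ConfusionTable,
    margin: Literal["sensitivity", "specificity"],
    stratum_labels: tuple[str, str] = ("a", "b"),
) -> HomogeneityResult:
    """Test whether a margin (sensitivity or specificity) differs between strata.

    Builds the 2x2 (successes, failures) x stratum table.  Pearson chi-square
    without continuity correction when all expected counts are >= 5, otherwise
    the two-sided Fisher exact test.
    """
    sa, fa = _margin_counts(ct_a, margin)
    sb, fb = _margin_counts(ct_b, margin)
    if sa + fa == 0 or sb + fb == 0:
        raise UndefinedStatisticError("empty stratum for homogeneity test")
    table = np.array([[sa, fa], [sb, fb]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected >= 5.0).all():
        chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
        return HomogeneityResult(float(chi2), float(p), "pearson_chi2", stratum_labels)
    _, p = sps.fisher_exact(table.astype(int), alternative="two-sided")
    return HomogeneityResult(None, float(p), "fisher_exact", stratum_labels)


def rogan_gladen(apparent: float, sn: float, sp: float) -> PrevalenceAdjustment:
    """Rogan-Gladen misclassification adjustment of an apparent prevalence.

    true = (apparent + sp - 1) / (sn + sp - 1), clamped to [0, 1].  The
    under-registration percentage is 100 * (true - apparent) / apparent.
    """
    denom = sn + sp - 1.0
    if abs(denom) < 1e-12:
        raise UndefinedStatisticError("Rogan-Gladen undefined for a non-informative test (sn + sp = 1)")
    true = (apparent + sp - 1.0) / denom
    true = min(1.0, max(0.0, true))
    under = 100.0 * (true - apparent) / apparent if apparent > 0 else None
    return PrevalenceAdjustment(apparent=apparent, sn=sn, sp=sp, true_prevalence=true,
                                under_registration_pct=under)


def predictive_values_at_prevalence(sn: float, sp: float, prevalence: float) -> tuple[float, float]:
    """Bayes predictive values of a test with given sn/sp at a given prevalence.

    ppv = p*sn / (p*sn + (1-p)(1-sp)); npv = (1-p)*sp / ((1-p)*sp + p*(1-sn)).
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must be in [0, 1], got {prevalence}")
    p, q = prevalence, 1.0 - prevalence
    den_ppv = p * sn + q * (1.0 - sp)
    den_npv = q * sp + p * (1.0 - sn)
    if den_ppv == 0.0 or den_npv == 0.0:
        raise UndefinedStatisticError("predictive value undefined: degenerate sn/sp at this prevalence")
    return p * sn / den_ppv, q * sp / den_npv


def predictive_value_intervals(
    sn: ProportionEstimate,
    sp: ProportionEstimate,
    prevalence: float,
    confidence: float = 0.95,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Approximate CIs for Bayes predictive values at a fixed prevalence.

    Propagates the Wilson-interval variances of sn and sp through the Bayes
    formulas by a delta method on the logit scale.  This is the package's own
    uncertainty approximation; it is not the (unpublished) method behind any
    published predictive-value intervals and does not reproduce them.

    Returns ``((ppv, lo, hi), (npv, lo, hi))``.
    """
    z = float(sps.norm.ppf(0.5 + confidence / 2))
    var_sn = ((sn.ci_high - sn.ci_low) / (2 * z)) ** 2
    var_sp = ((sp.ci_high - sp.ci_low) / (2 * z)) ** 2
    p, q = prevalence, 1.0 - prevalence
    ppv, npv = predictive_values_at_prevalence(sn.estimate, sp.estimate, prevalence)

    def _logit_ci(value: float, d_sn: float, d_sp: float) -> tuple[float, float]:
        var = d_sn**2 * var_sn + d_sp**2 * var_sp
        if value <= 0.0 or value >= 1.0 or var == 0.0:
            return value, value
        se_logit = math.sqrt(var) / (value * (1.0 - value))
        logit = math.log(value / (1.0 - value))
        lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
        return lo, hi

    a = p * sn.estimate
    b = q * (1.0 - sp.estimate)
    d_ppv_sn = p * b / (a + b) ** 2
    d_ppv_sp = a * q / (a + b) ** 2
    c = q * sp.estimate
    d = p * (1.0 - sn.estimate)
    d_npv_sp = q * d / (c + d) ** 2
    d_npv_sn = c * p / (c + d) ** 2

    ppv_lo, ppv_hi = _logit_ci(ppv, d_ppv_sn, d_ppv_sp)
    npv_lo, npv_hi = _logit_ci(npv, d_npv_sn, d_npv_sp)
    return (ppv, ppv_lo, ppv_hi), (npv, npv_lo, npv_hi)


def prevalence_grid(sn: float, sp: float, prevalences: Iterable[float]) -> pd.DataFrame:
    """Predictive values over a grid of assumed true prevalences."""
    prevalences = list(prevalences)
    if not prevalences:
        raise ValueError("prevalences must be non-empty")
    rows = []
    for p in prevalences:
        ppv, npv = predictive_values_at_prevalence(sn, sp, p)
        rows.append((p, ppv, npv))
    return pd.DataFrame(rows, columns=["prevalence", "ppv", "npv"])


# ---------------------------------------------------------------------------
# Stratified validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class ClassifiedSubject:
    """One validated subject: arm, gold-standard status and stratifiers."""

    patient_id: str
    arm: Literal["coded", "uncoded"]
    status: Status
    sex: str
    age: int
    dm: bool


@dataclass(slots=True)
class StratumResult:
    label: str
    table: ConfusionTable
    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    kappa: KappaEstimate | None


@dataclass(slots=True)
class ValidationReport:
    """Per-stratum diagnostic accuracy plus between-strata homogeneity tests."""

    disease: str
    strata: dict[str, StratumResult]
    homogeneity: dict[str, HomogeneityResult] = field(default_factory=dict)
    prevalence_adjustment: PrevalenceAdjustment | None = None
    grid: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _prop(e: ProportionEstimate | None):
            if e is None:
                return None
            return {"estimate": e.estimate, "ci_low": e.ci_low, "ci_high": e.ci_high,
                    "n": e.n, "method": e.method}

        out = {
            "disease": self.disease,
            "strata": {
                label: {
                    "counts": {"tp": s.table.tp, "fp": s.table.fp,
                               "fn": s.table.fn, "tn": s.table.tn},
                    "sensitivity": _prop(s.sensitivity),
                    "specificity": _prop(s.specificity),
                    "kappa": None if s.kappa is None else {
                        "kappa": s.kappa.kappa, "ci_low": s.kappa.ci_low,
                        "ci_high": s.kappa.ci_high, "po": s.kappa.po,
                        "pe": s.kappa.pe, "label": s.kappa.label,
                    },
                }
                for label, s in self.strata.items()
            },
            "homogeneity": {
                key: {"statistic": h.statistic, "p_value": h.p_value, "method": h.method,
                      "strata": list(h.stratum_labels)}
                for key, h in self.homogeneity.items()
            },
            "extras": self.extras,
        }
        if self.prevalence_adjustment is not None:
            pa = self.prevalence_adjustment
            out["prevalence_adjustment"] = {
                "apparent": pa.apparent, "sn": pa.sn, "sp": pa.sp,
                "true_prevalence": pa.true_prevalence,
                "under_registration_pct": pa.under_registration_pct,
            }
        if self.grid is not None:
            out["prevalence_grid"] = self.grid.to_dict(orient="records")
        return out


def _stratum_result(label: str, subjects: list[ClassifiedSubject], confidence: float) -> StratumResult:
    coded = [s for s in subjects if s.arm == "coded"]
    uncoded = [s for s in subjects if s.arm == "uncoded"]
    ct = build_confusion([CriteriaResult(s.status, ["x"] if s.status is Status.POSITIVE else [])
                          for s in coded],
                         [CriteriaResult(s.status, ["x"] if s.status is Status.POSITIVE else [])
                          for s in uncoded])

    def _try(fn):
        try:
            return fn(ct, confidence)
        except UndefinedStatisticError:
            return None

    return StratumResult(label, ct, _try(sensitivity), _try(specificity), _try(cohen_kappa))


def stratified_validation(
    subjects: Sequence[ClassifiedSubject],
    disease: str,
    age_cut: int = 70,
    confidence: float = 0.95,
) -> ValidationReport:
    """Overall and stratified accuracy with pairwise homogeneity tests.

    Strata: sex (male/female), age band (< age_cut / >= age_cut) and, for
    hypertension-style analyses, diabetes status.  A stratum whose margin is
    empty gets its statistic flagged as not computable and the run continues;
    homogeneity tests are only emitted when both complementary strata allow
    the margin.
    """
    subjects = [s for s in subjects if s.status is not Status.INELIGIBLE]
    report = ValidationReport(disease=disease, strata={}, homogeneity={})
    report.strata["overall"] = _stratum_result("overall", list(subjects), confidence)

    pairs: list[tuple[str, str, str, list, list]] = []
    male = [s for s in subjects if s.sex == "male"]
    female = [s for s in subjects if s.sex == "female"]
    young = [s for s in subjects if s.age < age_cut]
    old = [s for s in subjects if s.age >= age_cut]
    pairs.append(("sex", "male", "female", male, female))
    pairs.append(("age", f"age<{age_cut}", f"age>={age_cut}", young, old))
    if disease.upper() == "HTN":
        without = [s for s in subjects if not s.dm]
        with_dm = [s for s in subjects if s.dm]
        pairs.append(("dm", "without_dm", "with_dm", without, with_dm))

    for key, label_a, label_b, group_a, group_b in pairs:
        if not group_a or not group_b:
            continue  # single-stratum input: nothing to compare
        res_a = _stratum_result(label_a, group_a, confidence)
        res_b = _stratum_result(label_b, group_b, confidence)
        report.strata[label_a] = res_a
        report.strata[label_b] = res_b
        for margin in ("sensitivity", "specificity"):
            try:
                report.homogeneity[f"{margin}_by_{key}"] = homogeneity_test(
                    res_a.table, res_b.table, margin, (label_a, label_b)
                )
            except UndefinedStatisticError:
                pass
    return report


# ---------------------------------------------------------------------------
# Design-corrected recovery of population coding accuracy
# ---------------------------------------------------------------------------


@dataclass(frozen=True, slots=True)
class StratumCounts:
    """Per-stratum inputs for the design-corrected coding-accuracy estimator.

    ``n_coded`` / ``n_uncoded`` are the population counts of coded / uncoded
    patients in the stratum; the remaining fields are the sampled (eligible)
    subjects and how many of them are gold-standard positive.
    """

    label: str
    n_coded: int
    n_uncoded: int
    sampled_coded: int
    positive_coded: int
    sampled_uncoded: int
    positive_uncoded: int


def design_corrected_accuracy(
    strata: Sequence[StratumCounts], confidence: float = 0.95
) -> tuple[ProportionEstimate, ProportionEstimate]:
    """Estimate population coding sensitivity and specificity from code-based samples.

    Sampling one arm from the coded patients and one from the uncoded
    patients (case-control on the code, here additionally matched) makes the
    pooled TP/(TP+FN) of the two arms estimate a design-dependent quantity,
    not the population probability that a true case is coded.  This estimator
    removes that distortion by inverse-sampling-fraction weighting within
    post-strata: each stratum's sampled positivity is scaled back to its
    population coded/uncoded counts before pooling, which is consistent for
    the population-level P(code | gold+) and P(no code | gold-) provided the
    matching is no coarser than the strata.

    The interval propagates per-stratum Wilson bounds monotonically through
    the pooling ratio (wider than an exact interval, hence conservative).

    Returns ``(sensitivity, specificity)`` with the weighted point estimates;
    the reported ``n`` is the total number of sampled subjects informing each
    margin.
    """
    tp = fn = fp = tn = 0.0
    tp_lo = tp_hi = fn_lo = fn_hi = 0.0
    fp_lo = fp_hi = tn_lo = tn_hi = 0.0
    n_info = 0
    for s in strata:
        if s.sampled_coded > 0 and s.n_coded > 0:
            w = wilson_interval(s.positive_coded, s.sampled_coded, confidence)
            tp += s.n_coded * w.estimate
            tp_lo += s.n_coded * w.ci_low
            tp_hi += s.n_coded * w.ci_high
            fp += s.n_coded * (1 - w.estimate)
            fp_lo += s.n_coded * (1 - w.ci_high)
            fp_hi += s.n_coded * (1 - w.ci_low)
            n_info += s.sampled_coded
        if s.sampled_uncoded > 0 and s.n_uncoded > 0:
            w = wilson_interval(s.positive_uncoded, s.sampled_uncoded, confidence)
            fn += s.n_uncoded * w.estimate
            fn_lo += s.n_uncoded * w.ci_low
            fn_hi += s.n_uncoded * w.ci_high
            tn += s.n_uncoded * (1 - w.estimate)
            tn_lo += s.n_uncoded * (1 - w.ci_high)
            tn_hi += s.n_uncoded * (1 - w.ci_low)
            n_info += s.sampled_uncoded
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedStatisticError("no information on one of the margins")

    sn_hat = tp / (tp + fn)
    sn_lo = tp_lo / (tp_lo + fn_hi) if tp_lo + fn_hi > 0 else 0.0
    sn_hi = tp_hi / (tp_hi + fn_lo) if tp_hi + fn_lo > 0 else 1.0
    sp_hat = tn / (tn + fp)
    sp_lo = tn_lo / (tn_lo + fp_hi) if tn_lo + fp_hi > 0 else 0.0
    sp_hi = tn_hi / (tn_hi + fp_lo) if tn_hi + fp_lo > 0 else 1.0
    sn_est = ProportionEstimate(sn_hat, min(sn_lo, sn_hat), max(sn_hi, sn_hat), n_info,
                                method="post_stratified_wilson")
    sp_est = ProportionEstimate(sp_hat, min(sp_lo, sp_hat), max(sp_hi, sp_hat), n_info,
                                method="post_stratified_wilson")
    return sn_est, sp_est
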