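"""Diagnostic-accuracy statistics: printed-table reproduction, independent
oracles, and structural properties."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import hypergeom

from phenoval import (
    ConfusionTable,
    build_confusion,
    cohen_kappa,
    homogeneity_test,
    npv_direct,
    ppv_direct,
    predictive_values_at_prevalence,
    prevalence_grid,
    rogan_gladen,
    sensitivity,
    specificity,
    wilson_interval,
)
from phenoval.criteria import CriteriaResult, Status
from phenoval.stats import UndefinedStatisticError, landis_koch_label


def _results(n_pos: int, n_neg: int) -> list[CriteriaResult]:
    return [CriteriaResult(Status.POSITIVE, ["x"])] * n_pos + [
        CriteriaResult(Status.NEGATIVE)
    ] * n_neg


class TestBuildConfusion:
    def test_two_arm_cross_tabulation(self):
        ct = build_confusion(_results(421, 2), _results(2, 390))
        assert (ct.tp, ct.fp, ct.fn, ct.tn) == (421, 2, 2, 390)

    def test_empty_arms_all_zero(self):
        ct = build_confusion([], [])
        assert ct.n == 0

    def test_all_negative_coded_arm(self):
        assert build_confusion(_results(0, 10), _results(0, 5)).tp == 0

    def test_ineligible_results_rejected(self):
        with pytest.raises(ValueError, match="ineligible"):
            build_confusion([CriteriaResult(Status.INELIGIBLE)], [])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, fp=0, fn=0, tn=0)


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "x, n, expected",
        [
            (421, 423, (0.9953, 0.9829, 0.9987)),
            (415, 487, (0.8522, 0.8179, 0.8809)),
            (390, 392, (0.9949, 0.9816, 0.9986)),
        ],
    )
    def test_reproduces_published_intervals(self, x, n, expected):
        est = wilson_interval(x, n)
        assert (round(est.estimate, 4), round(est.ci_low, 4), round(est.ci_high, 4)) == expected

    def test_zero_successes_has_exact_zero_lower_bound(self):
        est = wilson_interval(0, 50)
        assert est.ci_low == 0.0 and est.estimate == 0.0 and est.ci_high > 0.0

    def test_zero_trials_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            wilson_interval(0, 0)

    @given(n=st.integers(1, 500), frac=st.floats(0.0, 1.0))
    def test_contains_estimate_and_shrinks_with_n(self, n, frac):
        x = round(n * frac)
        small = wilson_interval(x, n)
        assert small.ci_low <= small.estimate <= small.ci_high
        big = wilson_interval(10 * x, 10 * n)
        assert (big.ci_high - big.ci_low) <= (small.ci_high - small.ci_low) + 1e-12


class TestAccuracyMargins:
    def test_published_dm_table(self):
        ct = ConfusionTable(421, 2, 2, 390)
        assert round(100 * sensitivity(ct).estimate, 2) == 99.53
        assert round(100 * specificity(ct).estimate, 2) == 99.49

    def test_published_htn_table(self):
        ct = ConfusionTable(415, 8, 72, 254)
        assert round(100 * sensitivity(ct).estimate, 2) == 85.22
        assert round(100 * specificity(ct).estimate, 2) == 96.95

    def test_degenerate_sensitivity_is_zero(self):
        assert sensitivity(ConfusionTable(0, 0, 5, 0)).estimate == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedStatisticError):
            sensitivity(ConfusionTable(0, 3, 0, 7))

    @given(st.tuples(st.integers(0, 50), st.integers(0, 50),
                     st.integers(0, 50), st.integers(0, 50)))
    def test_transposition_swaps_margins(self, cells):
        """Swapping fp and fn swaps sensitivity with PPV and specificity with NPV."""
        tp, fp, fn, tn = cells
        ct = ConfusionTable(tp, fp, fn, tn)
        sw = ct.transpose()

        def maybe(fn_, table):
            try:
                return fn_(table).estimate
            except UndefinedStatisticError:
                return None

        assert maybe(sensitivity, ct) == maybe(ppv_direct, sw)
        assert maybe(specificity, ct) == maybe(npv_direct, sw)


class TestCohenKappa:
    @pytest.mark.parametrize(
        "cells, kappa3, ci3, label",
        [
            ((421, 2, 2, 390), 0.990, (0.981, 1.000), "almost perfect"),
            ((415, 8, 72, 254), 0.778, (0.732, 0.823), "substantial"),
            ((103, 1, 26, 22), 0.522, (0.376, 0.668), "moderate"),
        ],
    )
    def test_reproduces_published_kappas(self, cells, kappa3, ci3, label):
        est = cohen_kappa(ConfusionTable(*cells))
        assert round(est.kappa, 3) == kappa3
        assert (round(est.ci_low, 3), round(est.ci_high, 3)) == ci3
        assert est.label == label

    def test_perfect_diagonal(self):
        assert cohen_kappa(ConfusionTable(10, 0, 0, 10)).kappa == pytest.approx(1.0)

    def test_independence_table(self):
        assert cohen_kappa(ConfusionTable(25, 25, 25, 25)).kappa == pytest.approx(0.0)

    def test_degenerate_margins_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            cohen_kappa(ConfusionTable(10, 0, 0, 0))

    def test_exhaustive_agreement_with_margin_arithmetic(self):
        """po and pe match a from-scratch computation on every table with n <= 30,
        and kappa = 1 exactly when the off-diagonal is empty (non-degenerate)."""
        for n in range(1, 31):
            for tp in range(n + 1):
                for fp in range(n - tp + 1):
                    for fn in range(n - tp - fp + 1):
                        tn = n - tp - fp - fn
                        row1, col1 = tp + fp, tp + fn
                        pe = (row1 * col1 + (n - row1) * (n - col1)) / n**2
                        if pe >= 1.0 - 1e-15:
                            continue
                        est = cohen_kappa(ConfusionTable(tp, fp, fn, tn))
                        assert est.po == pytest.approx((tp + tn) / n)
                        assert est.pe == pytest.approx(pe)
                        assert est.kappa == pytest.approx(
                            ((tp + tn) / n - pe) / (1 - pe)
                        )
                        assert (est.kappa == pytest.approx(1.0)) == (fp == 0 and fn == 0)

    def test_matches_sklearn_on_random_tables(self):
        """Independent cross-check against scikit-learn's kappa on label vectors."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(25):
            tp, fp, fn, tn = rng.integers(1, 40, size=4)
            y_code = [1] * (tp + fp) + [0] * (fn + tn)
            y_gold = [1] * tp + [0] * fp + [1] * fn + [0] * tn
            ours = cohen_kappa(ConfusionTable(int(tp), int(fp), int(fn), int(tn))).kappa
            theirs = sklearn_metrics.cohen_kappa_score(y_code, y_gold)
            assert ours == pytest.approx(theirs, abs=1e-12)

    def test_label_bands(self):
        assert landis_koch_label(0.15) == "slight"
        assert landis_koch_label(0.30) == "fair"
        assert landis_koch_label(0.522) == "moderate"
        assert landis_koch_label(0.778) == "substantial"
        assert landis_koch_label(0.95) == "almost perfect"


class TestHomogeneity:
    def test_age_strata_pearson(self):
        """Sensitivity difference across age strata of the published table:
        chi-square without continuity correction, p about 0.007."""
        a = ConfusionTable(tp=173, fp=0, fn=18, tn=0)
        b = ConfusionTable(tp=242, fp=0, fn=54, tn=0)
        res = homogeneity_test(a, b, "sensitivity")
        assert res.method == "pearson_chi2"
        assert round(res.p_value, 3) == 0.007

    def test_dm_strata_pearson(self):
        a = ConfusionTable(tp=312, fp=0, fn=46, tn=0)
        b = ConfusionTable(tp=103, fp=0, fn=26, tn=0)
        res = homogeneity_test(a, b, "sensitivity")
        assert res.method == "pearson_chi2"
        assert round(res.p_value, 3) == 0.045

    def test_identical_strata(self):
        a = ConfusionTable(tp=50, fp=0, fn=10, tn=0)
        res = homogeneity_test(a, a, "sensitivity")
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_sparse_table_switches_to_fisher(self):
        a = ConfusionTable(tp=207, fp=0, fn=1, tn=0)
        b = ConfusionTable(tp=214, fp=0, fn=1, tn=0)
        res = homogeneity_test(a, b, "sensitivity")
        assert res.method == "fisher_exact"
        assert res.statistic is None
        assert res.p_value == pytest.approx(1.0)

    def test_empty_stratum_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            homogeneity_test(ConfusionTable(0, 0, 0, 5), ConfusionTable(5, 0, 5, 0),
                             "sensitivity")

    def test_fisher_matches_hypergeometric_enumeration(self):
        """Two-sided Fisher p equals an explicit sum over the conditional
        (hypergeometric) distribution of tables with the observed margins."""
        def fisher_oracle(s1, f1, s2, f2):
            row1, total, col1 = s1 + f1, s1 + f1 + s2 + f2, s1 + s2
            dist = hypergeom(total, col1, row1)
            p_obs = dist.pmf(s1)
            lo, hi = max(0, row1 + col1 - total), min(row1, col1)
            return sum(dist.pmf(k) for k in range(lo, hi + 1)
                       if dist.pmf(k) <= p_obs * (1 + 1e-9))

        rng = np.random.default_rng(1)
        for _ in range(40):
            s1, f1, s2, f2 = (int(v) for v in rng.integers(0, 8, size=4))
            if s1 + f1 == 0 or s2 + f2 == 0:
                continue
            a = ConfusionTable(tp=s1, fp=0, fn=f1, tn=0)
            b = ConfusionTable(tp=s2, fp=0, fn=f2, tn=0)
            res = homogeneity_test(a, b, "sensitivity")
            if res.method == "fisher_exact":
                assert res.p_value == pytest.approx(
                    fisher_oracle(s1, f1, s2, f2), abs=1e-9
                )


class TestRoganGladen:
    def test_perfect_test_identity(self):
        adj = rogan_gladen(0.123, 1.0, 1.0)
        assert adj.true_prevalence == pytest.approx(0.123)

    def test_printed_formula_on_published_inputs(self):
        """Direct evaluation with the published apparent prevalence and the
        unrounded Sn/Sp gives 13.46%."""
        adj = rogan_gladen(0.1411, 415 / 487, 254 / 262)
        assert round(adj.true_prevalence, 4) == 0.1346

    def test_negative_numerator_clamps_to_zero(self):
        adj = rogan_gladen(0.01, 0.85, 0.97)
        assert adj.true_prevalence == 0.0

    def test_non_informative_test_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            rogan_gladen(0.2, 0.3, 0.7)

    def test_under_registration_percentage(self):
        adj = rogan_gladen(0.10, 0.8, 0.99)
        expected = 100 * (adj.true_prevalence - 0.10) / 0.10
        assert adj.under_registration_pct == pytest.approx(expected)

    @given(p=st.floats(0.0, 1.0), sn=st.floats(0.55, 1.0), sp=st.floats(0.55, 1.0))
    def test_algebraic_round_trip(self, p, sn, sp):
        """Feeding the forward-misclassified apparent prevalence back through
        the adjustment recovers the latent prevalence."""
        apparent = sn * p + (1 - sp) * (1 - p)
        adj = rogan_gladen(apparent, sn, sp)
        assert adj.true_prevalence == pytest.approx(p, abs=1e-9)


class TestPredictiveValues:
    def test_boundary_contract(self):
        ppv, npv = predictive_values_at_prevalence(0.9, 0.95, 0.0)
        assert (ppv, npv) == (0.0, 1.0)
        ppv, npv = predictive_values_at_prevalence(0.9, 0.95, 1.0)
        assert (ppv, npv) == (1.0, 0.0)

    def test_degenerate_combination_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            predictive_values_at_prevalence(0.9, 1.0, 0.0)  # 0/0 at p = 0

    @given(sn=st.floats(0.01, 0.99), sp=st.floats(0.01, 0.99))
    def test_strict_monotonicity_in_prevalence(self, sn, sp):
        grid = prevalence_grid(sn, sp, [i / 20 for i in range(1, 20)])
        assert (grid["ppv"].diff().dropna() > 0).all()
        assert (grid["npv"].diff().dropna() < 0).all()

    def test_grid_shape_and_single_point(self):
        grid = prevalence_grid(0.9, 0.9, [0.0])
        assert list(grid.columns) == ["prevalence", "ppv", "npv"]
        assert len(grid) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            prevalence_grid(0.9, 0.9, [])
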