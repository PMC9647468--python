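"""Validation-statistics tests: published-table reproductions, brute-force
oracles, cross-checks against statsmodels, and distributional invariants."""

import math

import numpy as np
import pytest
from scipy import stats

from nutriscreen import (
    ContingencyTable2x2,
    ValidationError,
    cohens_kappa,
    correlation,
    diagnostic_metrics,
    diagnostic_report,
    grade_cc,
    grade_kappa,
    grade_sens_spec,
    mcnemar_test,
    paired_agreement,
    table_from_pairs,
)
from conftest import random_tables


# --------------------------------------------------------------------------
# table_from_pairs
# --------------------------------------------------------------------------


def test_single_pair_tally():
    t = table_from_pairs([True], [True])
    assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 0, 0)


def test_vectors_realizing_published_nrs_counts():
    idx = [True] * 34 + [True] * 47 + [False] * 8 + [False] * 155
    ref = [True] * 34 + [False] * 47 + [True] * 8 + [False] * 155
    t = table_from_pairs(idx, ref)
    assert (t.tp, t.fp, t.fn, t.tn) == (34, 47, 8, 155)
    assert t.n == 244


def test_tally_matches_brute_force(rng):
    for _ in range(20):
        idx = rng.random(50) < 0.4
        ref = rng.random(50) < 0.3
        t = table_from_pairs(idx, ref)
        # brute-force pairwise count
        counts = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for i, r in zip(idx, ref):
            counts[{(1, 1): "tp", (1, 0): "fp", (0, 1): "fn", (0, 0): "tn"}[(i, r)]] += 1
        assert (t.tp, t.fp, t.fn, t.tn) == tuple(counts.values())


def test_tally_input_validation():
    with pytest.raises(ValidationError):
        table_from_pairs([True], [True, False])
    with pytest.raises(ValidationError):
        table_from_pairs([], [])


# --------------------------------------------------------------------------
# 2x2 metrics
# --------------------------------------------------------------------------


def test_published_nrs_metrics(nrs_table):
    m = diagnostic_metrics(nrs_table)
    rounded = {k: round(100 * v.value, 1) for k, v in m.items()}
    assert rounded == {
        "accuracy": 77.5,
        "sensitivity": 81.0,
        "specificity": 76.7,
        "ppv": 42.0,
        "npv": 95.1,
    }


def test_published_pg_metrics(pg_table):
    m = diagnostic_metrics(pg_table)
    rounded = {k: round(100 * v.value, 1) for k, v in m.items()}
    assert rounded == {
        "accuracy": 69.3,
        "sensitivity": 84.5,
        "specificity": 64.5,
        "ppv": 42.6,
        "npv": 93.0,
    }


@pytest.mark.parametrize("k,m", [(1, 1), (5, 17), (100, 3)])
def test_perfect_agreement_all_metrics_one(k, m):
    metrics = diagnostic_metrics(ContingencyTable2x2(k, 0, 0, m))
    assert all(est.value == 1.0 for est in metrics.values())
    assert cohens_kappa(ContingencyTable2x2(k, 0, 0, m)).value == pytest.approx(1.0)


def test_zero_denominator_flagged_not_nan():
    t = ContingencyTable2x2(0, 5, 0, 10)  # no reference positives
    m = diagnostic_metrics(t)
    assert not m["sensitivity"].defined and m["sensitivity"].value is None
    assert m["specificity"].defined


def test_metrics_match_first_principles_oracle(rng):
    for t in random_tables(rng, 1000):
        m = diagnostic_metrics(t)
        n = t.tp + t.fp + t.fn + t.tn
        assert abs(m["accuracy"].value - (t.tp + t.tn) / n) < 1e-12
        assert abs(m["sensitivity"].value - t.tp / (t.tp + t.fn)) < 1e-12
        assert abs(m["specificity"].value - t.tn / (t.tn + t.fp)) < 1e-12
        assert abs(m["ppv"].value - t.tp / (t.tp + t.fp)) < 1e-12
        assert abs(m["npv"].value - t.tn / (t.tn + t.fn)) < 1e-12


def test_bayes_consistency_of_ppv(rng):
    for t in random_tables(rng, 200):
        m = diagnostic_metrics(t)
        prev = (t.tp + t.fn) / t.n
        sens, spec = m["sensitivity"].value, m["specificity"].value
        ppv_analytic = sens * prev / (sens * prev + (1 - spec) * (1 - prev))
        assert abs(ppv_analytic - m["ppv"].value) < 1e-12


def test_ci_width_shrinks_when_counts_scaled(rng, nrs_table):
    for ci_method in ("clopper-pearson", "wilson"):
        small = diagnostic_metrics(nrs_table, ci_method=ci_method)
        big = diagnostic_metrics(
            ContingencyTable2x2(340, 470, 80, 1550), ci_method=ci_method
        )
        for key in small:
            w_small = small[key].ci_high - small[key].ci_low
            w_big = big[key].ci_high - big[key].ci_low
            assert w_big < w_small
    k_small = cohens_kappa(nrs_table)
    k_big = cohens_kappa(ContingencyTable2x2(340, 470, 80, 1550))
    assert (k_big.ci_high - k_big.ci_low) < (k_small.ci_high - k_small.ci_low)


# --------------------------------------------------------------------------
# Cohen's kappa
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "cells,expected",
    [((34, 47, 8, 155), 0.42), ((49, 66, 9, 120), 0.37)],
)
def test_published_kappa_values(cells, expected):
    assert round(cohens_kappa(ContingencyTable2x2(*cells)).value, 2) == expected


def test_kappa_rater_symmetry(rng):
    for t in random_tables(rng, 100):
        swapped = ContingencyTable2x2(t.tp, t.fn, t.fp, t.tn)  # swap rater roles
        assert cohens_kappa(t).value == pytest.approx(cohens_kappa(swapped).value)
        assert cohens_kappa(t).value <= 1.0


def test_kappa_one_iff_no_discordance(rng):
    for t in random_tables(rng, 100):
        k = cohens_kappa(t).value
        if t.fp == 0 and t.fn == 0:
            assert k == pytest.approx(1.0)
        else:
            assert k < 1.0


def test_kappa_degenerate_margins_flagged():
    res = cohens_kappa(ContingencyTable2x2(7, 0, 0, 0))
    assert not res.defined


def test_kappa_and_se_cross_check_against_statsmodels(rng):
    from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

    for t in random_tables(rng, 50):
        ours = cohens_kappa(t)
        theirs = sm_kappa(t.as_array(), return_results=True)
        assert ours.value == pytest.approx(float(theirs.kappa), abs=1e-10)
        se_ours = (ours.ci_high - ours.ci_low) / (2 * stats.norm.ppf(0.975))
        # CI may have been clipped at +/-1; only compare unclipped tables
        if -1 < ours.ci_low and ours.ci_high < 1:
            assert se_ours == pytest.approx(float(theirs.var_kappa) ** 0.5, rel=1e-6)


# --------------------------------------------------------------------------
# McNemar
# --------------------------------------------------------------------------


def test_mcnemar_published_table_asymptotic(nrs_table):
    res = mcnemar_test(nrs_table, continuity_correction=False)
    assert res.statistic == pytest.approx((47 - 8) ** 2 / 55)
    assert res.p_value < 0.001
    assert res.method == "chi2"


def test_mcnemar_symmetric_discordance_is_null():
    res = mcnemar_test(ContingencyTable2x2(10, 30, 30, 10))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_mcnemar_no_discordance_degenerate():
    res = mcnemar_test(ContingencyTable2x2(10, 0, 0, 10))
    assert (res.statistic, res.p_value) == (0.0, 1.0)


def test_mcnemar_exact_small_table_matches_enumeration():
    res = mcnemar_test(ContingencyTable2x2(50, 3, 1, 50))
    # full enumeration of Binomial(4, 1/2): P(X<=1) + P(X>=3) = 10/16
    expected = sum(math.comb(4, k) for k in (0, 1, 3, 4)) / 2**4
    assert res.method == "exact-binomial"
    assert res.p_value == pytest.approx(expected)


def test_mcnemar_depends_only_on_discordant_cells(rng):
    for t in random_tables(rng, 50):
        other = ContingencyTable2x2(t.tn, t.fp, t.fn, t.tp)  # concordant swapped
        for cc in (False, True):
            a = mcnemar_test(t, continuity_correction=cc)
            b = mcnemar_test(other, continuity_correction=cc)
            assert (a.statistic, a.p_value) == (b.statistic, b.p_value)


def test_mcnemar_cross_check_against_statsmodels(rng):
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    for t in random_tables(rng, 30):
        exact = t.fp + t.fn < 25
        ours = mcnemar_test(t)
        theirs = sm_mcnemar(t.as_array(), exact=exact, correction=False)
        assert ours.p_value == pytest.approx(float(theirs.pvalue), abs=1e-10)


# --------------------------------------------------------------------------
# Correlation
# --------------------------------------------------------------------------


def test_correlation_identity_and_reflection(rng):
    x = rng.normal(size=30)
    assert correlation(x, x, method="pearson").value == pytest.approx(1.0)
    assert correlation(x, -x, method="pearson").value == pytest.approx(-1.0)


def test_spearman_equals_rank_then_pearson_oracle(rng):
    x = rng.normal(size=20)
    y = 0.6 * x + rng.normal(size=20)
    ours = correlation(x, y, method="spearman").value
    oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    assert ours == pytest.approx(oracle, abs=1e-12)


def test_auto_method_selection(rng):
    x = rng.normal(size=200)
    y = 0.5 * x + rng.normal(size=200)
    assert correlation(x, y, method="auto").method == "pearson"
    skewed = np.exp(rng.normal(size=200) * 2.0)
    assert correlation(skewed, np.exp(y) ** 2, method="auto").method == "spearman"


def test_zero_variance_flagged():
    res = correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert not res.defined


def test_correlation_ci_contains_point(rng):
    x = rng.normal(size=50)
    y = 0.4 * x + rng.normal(size=50)
    res = correlation(x, y, method="pearson")
    assert res.ci_low <= res.value <= res.ci_high


# --------------------------------------------------------------------------
# Paired agreement
# --------------------------------------------------------------------------


def test_identical_vectors_zero_difference():
    s = paired_agreement([1500.0, 1400.0, 1600.0], [1500.0, 1400.0, 1600.0])
    assert s.mean_difference == 0.0 and s.sd_difference == 0.0
    assert s.median_relative_pct == 0.0
    assert s.p_value == 1.0 and s.test_name == "degenerate"


def test_symmetric_construction():
    s = paired_agreement([110.0, 90.0], [100.0, 100.0])
    assert s.mean_difference == pytest.approx(0.0)
    assert s.median_relative_pct == pytest.approx(0.0)
    assert sorted(s.iqr_relative_pct) == pytest.approx([-5.0, 5.0])


def test_simulated_bias_recovered_within_three_se(rng):
    delta, sigma, n = 144.2, 454.8, 30
    ref = rng.normal(1434.1, 528.8, size=n)
    app = ref + delta + rng.normal(0.0, sigma, size=n)
    s = paired_agreement(app, ref)
    assert abs(s.mean_difference - delta) < 3 * sigma / math.sqrt(n)


def test_nonpositive_reference_pairs_excluded():
    s = paired_agreement([100.0, 120.0, 90.0], [0.0, 100.0, 100.0])
    assert s.n_excluded == 1 and s.n == 2
    all_bad = paired_agreement([1.0, 2.0], [0.0, -1.0])
    assert not all_bad.defined and all_bad.n == 0


# --------------------------------------------------------------------------
# Grading
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "sens,spec,grade",
    [
        (0.810, 0.767, "fair"),
        (0.845, 0.645, "fair"),
        (0.85, 0.85, "good"),
        (0.45, 0.9, "poor"),
        (0.80, 0.80, "fair"),  # boundary: must exceed 80%
        (None, 0.9, "undetermined"),
    ],
)
def test_sens_spec_grading(sens, spec, grade):
    assert grade_sens_spec(sens, spec) == grade


@pytest.mark.parametrize(
    "kappa,grade", [(0.42, "fair"), (0.37, "poor"), (0.60, "good"), (None, "undetermined")]
)
def test_kappa_grading(kappa, grade):
    assert grade_kappa(kappa) == grade


@pytest.mark.parametrize(
    "cc,grade", [(0.62, "fair"), (0.75, "good"), (0.39, "poor")]
)
def test_cc_grading(cc, grade):
    assert grade_cc(cc) == grade


def test_full_report_assembly(nrs_table):
    rep = diagnostic_report(nrs_table)
    d = rep.to_dict()
    assert d["grades"]["sens_spec"] == "fair"
    assert d["grades"]["kappa"] == "fair"
    assert d["cc"] is None and d["grades"]["cc"] == "undetermined"
    assert d["metrics"]["accuracy"]["value"] == pytest.approx(189 / 244)
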