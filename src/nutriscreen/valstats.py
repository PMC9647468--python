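"""Diagnostic-accuracy and agreement statistics for validation studies.

The unit of validation is the paired 2×2 table of an index test (the
self-administered app) against a reference test (dietitian-administered
screening) on the same patients.  This module computes the standard
machinery of such studies:

* accuracy, sensitivity, specificity, PPV, NPV with binomial CIs
  (Clopper–Pearson by default, Wilson optionally);
* Cohen's κ with a large-sample (Fleiss-type) standard-error CI;
* McNemar's test of marginal homogeneity (asymptotic χ², optional
  continuity correction, exact binomial for few discordant pairs);
* Pearson/Spearman correlation with Fisher-z CIs and automatic method
  choice by normality screening;
* paired-difference summaries for continuous intake comparisons;
* the good/fair/poor validity grading bands on sensitivity+specificity,
  correlation and κ.

Undefined statistics (zero denominators, degenerate margins) are returned
with an explicit ``defined=False`` flag and a note — never as silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "MetricEstimate",
    "McNemarResult",
    "CorrelationResult",
    "PairedAgreementSummary",
    "DiagnosticReport",
    "table_from_pairs",
    "diagnostic_metrics",
    "cohens_kappa",
    "mcnemar_test",
    "correlation",
    "paired_agreement",
    "grade_sens_spec",
    "grade_cc",
    "grade_kappa",
    "grade_validity",
    "diagnostic_report",
]

_ALPHA = 0.05


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Paired index-vs-reference classification counts.

    ``tp``: index+/reference+, ``fp``: index+/reference−,
    ``fn``: index−/reference+, ``tn``: index−/reference−.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValidationError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def index_positive(self) -> int:
        return self.tp + self.fp

    @property
    def reference_positive(self) -> int:
        return self.tp + self.fn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


def table_from_pairs(
    index_flags: Sequence[bool], reference_flags: Sequence[bool]
) -> ContingencyTable2x2:
    """Tally paired binary outcomes into a 2×2 table."""
    idx = np.asarray(index_flags, dtype=bool)
    ref = np.asarray(reference_flags, dtype=bool)
    if idx.shape != ref.shape or idx.ndim != 1:
        raise ValidationError("index and reference flags must be equal-length 1-D")
    if idx.size == 0:
        raise ValidationError("empty input")
    return ContingencyTable2x2(
        tp=int(np.sum(idx & ref)),
        fp=int(np.sum(idx & ~ref)),
        fn=int(np.sum(~idx & ref)),
        tn=int(np.sum(~idx & ~ref)),
    )


@dataclass(frozen=True)
class MetricEstimate:
    """Point estimate with two-sided 95% CI and an explicit defined flag."""

    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    defined: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.defined and self.value is None:
            raise ValidationError("defined metric must carry a value")

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "defined": self.defined,
            "note": self.note,
        }


def _proportion_metric(count: int, nobs: int, ci_method: str) -> MetricEstimate:
    if nobs == 0:
        return MetricEstimate(
            value=None, defined=False, note="zero denominator"
        )
    method = {"clopper-pearson": "beta", "wilson": "wilson"}.get(ci_method)
    if method is None:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    lo, hi = proportion_confint(count, nobs, alpha=_ALPHA, method=method)
    return MetricEstimate(value=count / nobs, ci_low=float(lo), ci_high=float(hi))


def diagnostic_metrics(
    table: ContingencyTable2x2, ci_method: str = "clopper-pearson"
) -> dict[str, MetricEstimate]:
    """Accuracy, sensitivity, specificity, PPV and NPV with binomial CIs."""
    t = table
    return {
        "accuracy": _proportion_metric(t.tp + t.tn, t.n, ci_method),
        "sensitivity": _proportion_metric(t.tp, t.tp + t.fn, ci_method),
        "specificity": _proportion_metric(t.tn, t.tn + t.fp, ci_method),
        "ppv": _proportion_metric(t.tp, t.tp + t.fp, ci_method),
        "npv": _proportion_metric(t.tn, t.tn + t.fn, ci_method),
    }


def cohens_kappa(table: ContingencyTable2x2) -> MetricEstimate:
    """Chance-corrected agreement κ = (p_o − p_e)/(1 − p_e), with a
    large-sample (Fleiss-type) standard-error 95% CI."""
    n = table.n
    if n < 2:
        return MetricEstimate(value=None, defined=False, note="n < 2")
    a, b, c, d = (x / n for x in (table.tp, table.fp, table.fn, table.tn))
    r1, r2 = a + b, c + d  # index margins
    c1, c2 = a + c, b + d  # reference margins
    p_o = a + d
    p_e = r1 * c1 + r2 * c2
    if math.isclose(p_e, 1.0):
        return MetricEstimate(
            value=None, defined=False, note="degenerate margins (p_e = 1)"
        )
    kappa = (p_o - p_e) / (1.0 - p_e)
    # Fleiss, Cohen & Everitt large-sample variance of kappa-hat.
    term_a = (
        a * ((1 - p_e) - (c1 + r1) * (1 - p_o)) ** 2
        + d * ((1 - p_e) - (c2 + r2) * (1 - p_o)) ** 2
    )
    term_b = (1 - p_o) ** 2 * (b * (c1 + r2) ** 2 + c * (c2 + r1) ** 2)
    term_c = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term_a + term_b - term_c) / (n * (1 - p_e) ** 4)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(1 - _ALPHA / 2)
    return MetricEstimate(
        value=kappa,
        ci_low=max(kappa - z * se, -1.0),
        ci_high=min(kappa + z * se, 1.0),
    )


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p_value: float
    method: str  # "chi2", "chi2-cc", "exact-binomial", "degenerate"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
        }


def mcnemar_test(
    table: ContingencyTable2x2,
    continuity_correction: bool = False,
    exact: str | bool = "auto",
) -> McNemarResult:
    """McNemar's test of marginal homogeneity for the paired design.

    Driven only by the discordant cells (fp, fn).  With ``exact="auto"``
    the exact binomial test replaces the χ² approximation when fewer than
    25 discordant pairs are observed.
    """
    b, c = table.fp, table.fn
    disc = b + c
    if disc == 0:
        return McNemarResult(statistic=0.0, p_value=1.0, method="degenerate")
    corr = 1.0 if continuity_correction else 0.0
    stat = max(abs(b - c) - corr, 0.0) ** 2 / disc
    use_exact = exact is True or (exact == "auto" and disc < 25)
    if use_exact:
        # two-sided exact binomial: double the smaller tail, capped at 1
        k = min(b, c)
        p = min(1.0, 2.0 * stats.binom.cdf(k, disc, 0.5))
        return McNemarResult(statistic=stat, p_value=float(p), method="exact-binomial")
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(
        statistic=stat,
        p_value=p,
        method="chi2-cc" if continuity_correction else "chi2",
    )


@dataclass(frozen=True)
class CorrelationResult:
    value: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    method: str = ""
    p_value: Optional[float] = None
    defined: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "method": self.method,
            "p_value": self.p_value,
            "defined": self.defined,
            "note": self.note,
        }


def _is_normal(x: np.ndarray, alpha: float = _ALPHA) -> bool:
    """Kolmogorov–Smirnov-type (Lilliefors) normality screen."""
    if x.size < 4 or np.ptp(x) == 0:
        return False  # too few observations to support normality
    from statsmodels.stats.diagnostic import lilliefors

    _, p = lilliefors(x, dist="norm", pvalmethod="approx")
    return p > alpha


def correlation(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> CorrelationResult:
    """Correlation with 95% CI via the Fisher z-transform.

    ``method="auto"`` picks Pearson when both margins pass the normality
    screen at α=0.05 and Spearman otherwise, mirroring common practice in
    validation studies.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D")
    n = xa.size
    if n < 3:
        raise ValidationError("correlation needs at least 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return CorrelationResult(
            value=None, method=method, defined=False, note="zero variance"
        )
    if method == "auto":
        method = "pearson" if (_is_normal(xa) and _is_normal(ya)) else "spearman"
    if method == "pearson":
        r, p = stats.pearsonr(xa, ya)
    elif method == "spearman":
        r, p = stats.spearmanr(xa, ya)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    r = float(r)
    if abs(r) >= 1.0 or n <= 3:
        lo, hi = r, r
    else:
        z = math.atanh(r)
        se = 1.0 / math.sqrt(n - 3)
        crit = stats.norm.ppf(1 - _ALPHA / 2)
        lo, hi = math.tanh(z - crit * se), math.tanh(z + crit * se)
    return CorrelationResult(
        value=r, ci_low=lo, ci_high=hi, method=method, p_value=float(p)
    )


@dataclass(frozen=True)
class PairedAgreementSummary:
    """Mean/SD of absolute differences, median/IQR of relative differences,
    correlation, and the paired test chosen by normality of the differences."""

    n: int
    n_excluded: int
    mean_difference: float
    sd_difference: float
    median_relative_pct: Optional[float]
    iqr_relative_pct: Optional[tuple[float, float]]
    correlation: CorrelationResult
    test_name: str
    p_value: Optional[float]
    defined: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_excluded": self.n_excluded,
            "mean_difference": self.mean_difference,
            "sd_difference": self.sd_difference,
            "median_relative_pct": self.median_relative_pct,
            "iqr_relative_pct": list(self.iqr_relative_pct)
            if self.iqr_relative_pct is not None
            else None,
            "correlation": self.correlation.to_dict(),
            "test_name": self.test_name,
            "p_value": self.p_value,
            "defined": self.defined,
            "note": self.note,
        }


def paired_agreement(
    app_values: Sequence[float], ref_values: Sequence[float]
) -> PairedAgreementSummary:
    """Agreement between app-estimated and reference-measured intakes.

    Differences are app − reference.  Relative differences (%) use the
    reference value as denominator per pair; pairs with a non-positive
    reference are excluded from the relative summary with the count logged.
    The location test is a paired t-test when the differences pass the
    normality screen, otherwise the Wilcoxon signed-rank test.
    """
    app = np.asarray(app_values, dtype=float)
    ref = np.asarray(ref_values, dtype=float)
    if app.shape != ref.shape or app.ndim != 1:
        raise ValidationError("paired vectors must be equal-length 1-D")
    if app.size < 2:
        raise ValidationError("paired agreement needs at least 2 pairs")
    d = app - ref
    usable = ref > 0
    n_excluded = int(np.sum(~usable))
    if n_excluded == app.size:
        return PairedAgreementSummary(
            n=0,
            n_excluded=n_excluded,
            mean_difference=float(np.mean(d)),
            sd_difference=float(np.std(d, ddof=1)),
            median_relative_pct=None,
            iqr_relative_pct=None,
            correlation=CorrelationResult(
                value=None, defined=False, note="no usable pairs"
            ),
            test_name="none",
            p_value=None,
            defined=False,
            note="all pairs excluded (reference <= 0)",
        )
    rel = 100.0 * d[usable] / ref[usable]
    q25, q50, q75 = np.percentile(rel, [25, 50, 75])
    if np.all(d == 0):
        test_name, p_value = "degenerate", 1.0
    elif _is_normal(d):
        test_name = "paired-t"
        p_value = float(stats.ttest_1samp(d, 0.0).pvalue)
    else:
        test_name = "wilcoxon"
        p_value = float(stats.wilcoxon(d).pvalue)
    if app.size >= 3:
        corr = correlation(app, ref, method="auto")
    else:
        corr = CorrelationResult(value=None, defined=False, note="fewer than 3 pairs")
    return PairedAgreementSummary(
        n=int(np.sum(usable)),
        n_excluded=n_excluded,
        mean_difference=float(np.mean(d)),
        sd_difference=float(np.std(d, ddof=1)),
        median_relative_pct=float(q50),
        iqr_relative_pct=(float(q25), float(q75)),
        correlation=corr,
        test_name=test_name,
        p_value=p_value,
    )


# ---------------------------------------------------------------------------
# Validity grading
# ---------------------------------------------------------------------------


def grade_sens_spec(sensitivity: Optional[float], specificity: Optional[float]) -> str:
    """Good: both > 80%.  Poor: either < 50%.  Fair otherwise."""
    if sensitivity is None or specificity is None:
        return "undetermined"
    if sensitivity > 0.80 and specificity > 0.80:
        return "good"
    if sensitivity < 0.50 or specificity < 0.50:
        return "poor"
    return "fair"


def grade_cc(cc: Optional[float]) -> str:
    """Good: CC ≥ 0.75.  Fair: 0.4 ≤ CC < 0.75.  Poor: CC < 0.4."""
    if cc is None:
        return "undetermined"
    if cc >= 0.75:
        return "good"
    if cc >= 0.40:
        return "fair"
    return "poor"


def grade_kappa(kappa: Optional[float]) -> str:
    """Good: κ ≥ 0.6.  Fair: 0.4 ≤ κ < 0.6.  Poor: κ < 0.4."""
    if kappa is None:
        return "undetermined"
    if kappa >= 0.60:
        return "good"
    if kappa >= 0.40:
        return "fair"
    return "poor"


@dataclass(frozen=True)
class DiagnosticReport:
    """Full per-instrument validation report (grades per criterion, never merged)."""

    table: ContingencyTable2x2
    metrics: dict[str, MetricEstimate]
    kappa: MetricEstimate
    mcnemar: McNemarResult
    cc: Optional[CorrelationResult]
    grade_sens_spec: str
    grade_kappa: str
    grade_cc: str

    def to_dict(self) -> dict:
        return {
            "table": {
                "tp": self.table.tp,
                "fp": self.table.fp,
                "fn": self.table.fn,
                "tn": self.table.tn,
                "n": self.table.n,
            },
            "metrics": {k: m.to_dict() for k, m in self.metrics.items()},
            "kappa": self.kappa.to_dict(),
            "mcnemar": self.mcnemar.to_dict(),
            "cc": self.cc.to_dict() if self.cc is not None else None,
            "grades": {
                "sens_spec": self.grade_sens_spec,
                "kappa": self.grade_kappa,
                "cc": self.grade_cc,
            },
        }


def grade_validity(report: "DiagnosticReport") -> dict[str, str]:
    """Apply the good/fair/poor bands to an assembled report."""
    return {
        "sens_spec": report.grade_sens_spec,
        "kappa": report.grade_kappa,
        "cc": report.grade_cc,
    }


def diagnostic_report(
    table: ContingencyTable2x2,
    ci_method: str = "clopper-pearson",
    continuity_correction: bool = False,
    index_scores: Optional[Sequence[float]] = None,
    reference_scores: Optional[Sequence[float]] = None,
) -> DiagnosticReport:
    """Assemble the complete validation report for one instrument.

    When per-patient scores are supplied the correlation coefficient is
    computed on them (method chosen by normality screening); otherwise the
    CC slot is left undefined rather than silently computed on flags.
    """
    metrics = diagnostic_metrics(table, ci_method=ci_method)
    kappa = cohens_kappa(table)
    mcn = mcnemar_test(table, continuity_correction=continuity_correction)
    cc: Optional[CorrelationResult] = None
    if index_scores is not None and reference_scores is not None:
        cc = correlation(index_scores, reference_scores, method="auto")
    return DiagnosticReport(
        table=table,
        metrics=metrics,
        kappa=kappa,
        mcnemar=mcn,
        cc=cc,
        grade_sens_spec=grade_sens_spec(
            metrics["sensitivity"].value, metrics["specificity"].value
        ),
        grade_kappa=grade_kappa(kappa.value),
        grade_cc=grade_cc(cc.value if cc is not None and cc.defined else None),
    )
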