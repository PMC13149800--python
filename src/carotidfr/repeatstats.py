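"""Scan-rescan repeatability and intermodality agreement statistics.

Repeatability of a metric measured twice in each subject is quantified
with the two-way random-effects, absolute-agreement, single-measurement
intraclass correlation ICC(2,1) (with an exact F-distribution confidence
interval) and the test-retest coefficient of variation (root-mean-square
of per-subject within-subject CV).  Agreement between modalities uses
Bland-Altman bias and 1.96-sd limits, ordinary least-squares regression
with Pearson r, and Shapiro-Wilk-gated paired tests (Student's t when
the paired differences look normal, Wilcoxon signed-rank otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RepeatabilityResult",
    "AgreementResult",
    "icc_2_1",
    "cv_testretest",
    "bland_altman",
    "regression_pearson",
    "paired_compare",
]


@dataclass
class RepeatabilityResult:
    icc: float
    ci95: tuple[float, float]
    cv_percent: float | None = None


@dataclass
class AgreementResult:
    bias: float | None = None
    loa: tuple[float, float] | None = None
    slope: float | None = None
    intercept: float | None = None
    pearson_r: float | None = None


def _anova_mean_squares(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) mean squares: rows, columns, error."""
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(measurements: np.ndarray, alpha: float = 0.05) -> RepeatabilityResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an (n_subjects, k_sessions) matrix with no
    missing cells.  The confidence interval follows the standard
    F-distribution bounds with a Satterthwaite-approximated denominator
    degree of freedom.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[0] < 3 or m.shape[1] < 2:
        raise ValueError("need an (n >= 3) x (k >= 2) matrix")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not supported")
    if np.allclose(m, m.flat[0]):
        raise ValueError("zero total variance: ICC undefined")
    n, k = m.shape
    msr, msc, mse = _anova_mean_squares(m)
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # exact F bounds (Shrout & Fleiss 1979; McGraw & Wong 1996)
    a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_star_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_star_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        # McGraw & Wong closed forms for ICC(A,1):
        lower = (
            n * (msr - f_star_u * mse)
            / (f_star_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        upper = (
            n * (f_star_l * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_star_l * msr)
        )
    else:
        lower, upper = icc, icc
    lower = min(lower, icc)
    upper = max(upper, icc)
    return RepeatabilityResult(icc=float(icc), ci95=(float(lower), float(min(upper, 1.0))))


def cv_testretest(measurements: np.ndarray) -> float:
    """Test-retest CV: RMS over subjects of within-subject sd / mean, in %."""
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2")
    means = m.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("subject means must be positive for a CV")
    sds = m.std(axis=1, ddof=1)
    return float(np.sqrt(np.mean((sds / means) ** 2)) * 100.0)


def bland_altman(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """Bland-Altman bias and 95% limits of agreement for paired data."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return AgreementResult(bias=bias, loa=(bias - 1.96 * sd, bias + 1.96 * sd))


def regression_pearson(a: np.ndarray, b: np.ndarray) -> AgreementResult:
    """OLS regression of b on a, with the Pearson correlation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need equal-length arrays with n >= 3")
    if np.var(a) == 0:
        raise ValueError("zero variance in the predictor")
    res = stats.linregress(a, b)
    return AgreementResult(
        slope=float(res.slope), intercept=float(res.intercept), pearson_r=float(res.rvalue)
    )


def paired_compare(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> tuple[str, float]:
    """Normality-gated two-sided paired comparison.

    Shapiro-Wilk on the paired differences decides between the paired
    Student's t-test (normal) and the Wilcoxon signed-rank test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 4:
        raise ValueError("need equal-length arrays with n >= 4")
    d = a - b
    if np.all(d == d[0]) and d[0] == 0:
        warnings.warn("all paired differences are zero; returning p = 1", RuntimeWarning,
                      stacklevel=2)
        return "degenerate", 1.0
    if np.all(d == d[0]):
        # constant non-zero difference: Shapiro-Wilk undefined, t-test degenerate
        return "t-test", 0.0
    sw_p = stats.shapiro(d).pvalue
    if sw_p > alpha:
        return "t-test", float(stats.ttest_rel(a, b).pvalue)
    return "wilcoxon", float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
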