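"""Paired-measure agreement statistics between device and reference summaries.

Given index-aligned per-participant measurements x (reference, PSG) and y
(test device), this module provides the Bland-Altman family (bias, limits of
agreement with confidence intervals, minimum detectable change), standardized
unitless metrics for cross-measure device ranking (SMAPE and SAD), correlation
and reliability (Pearson rho, single-measure consistency ICC from a two-way
model), effect sizes (paired and two-sample Cohen's d), a Shapiro-Wilk
normality check of the differences, magnitude classification, and the
satisfactory-agreement rule based on published inter-scorer ICC thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasures",
    "AgreementReport",
    "AgreementError",
    "bland_altman",
    "smape",
    "sad",
    "pearson",
    "icc_consistency",
    "cohen_d_paired",
    "cohen_d_two_sample",
    "normality_check",
    "classify_magnitude",
    "is_satisfactory_summary",
    "normal_ci",
    "compute_agreement",
    "SUMMARY_ICC_THRESHOLDS",
]

# Satisfactory-agreement ICC thresholds for summary duration measures, taken
# from published inter-scorer reliability of visual sleep scoring (the level
# two human scorers reach); a device is satisfactory when it exceeds them.
SUMMARY_ICC_THRESHOLDS: dict[str, float] = {
    "WASO": 0.84,
    "REM": 0.75,
    "NREM": 0.65,
    "LS": 0.67,
    "DS": 0.63,
}


class AgreementError(Exception):
    """Insufficient or degenerate data for an agreement statistic."""


@dataclass
class PairedMeasures:
    """Index-aligned reference (x) and test (y) values for one measure."""

    measure_name: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise AgreementError("x and y must be 1-D and index-aligned")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def d(self) -> np.ndarray:
        """Differences test - reference."""
        return self.y - self.x

    @property
    def s2_x(self) -> float:
        return float(np.var(self.x, ddof=1))

    @property
    def s2_y(self) -> float:
        return float(np.var(self.y, ddof=1))


@dataclass
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    mdc: float


@dataclass
class AgreementReport:
    """Full agreement panel for one (device, measure) cell."""

    measure_name: str
    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_bias: tuple[float, float]
    ci_loa_low: tuple[float, float]
    ci_loa_high: tuple[float, float]
    mdc: float
    rho: float
    icc: float
    cohen_d: float
    smape: float
    sad: float
    normality_w: float
    normality_p: float
    non_normal: bool
    satisfactory: bool | None


def bland_altman(p: PairedMeasures) -> BlandAltman:
    """Bland-Altman bias, 95% limits of agreement, their CIs, and the MDC.

    d_i = y_i - x_i; bias = mean(d); LOA = bias ± 1.96·SD(d).  The bias CI
    uses SE = SD/√n and each LOA CI uses SE = SD·√(3/n) (Bland & Altman's
    large-sample approximation).  MDC = 1.96·SD(d), the smallest change
    distinguishable from measurement noise in a single pair.
    """
    if p.n < 2:
        raise AgreementError(f"Bland-Altman requires n >= 2, got n={p.n}")
    d = p.d
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = 1.96 * sd
    se_bias = sd / math.sqrt(p.n)
    se_loa = sd * math.sqrt(3.0 / p.n)
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - half,
        loa_high=bias + half,
        ci_bias=(bias - 1.96 * se_bias, bias + 1.96 * se_bias),
        ci_loa_low=(bias - half - 1.96 * se_loa, bias - half + 1.96 * se_loa),
        ci_loa_high=(bias + half - 1.96 * se_loa, bias + half + 1.96 * se_loa),
        mdc=half,
    )


def smape(p: PairedMeasures) -> float:
    """Symmetric mean absolute percentage error, bounded in [0, 100].

    SMAPE = (100/n) Σ |x_i − y_i| / (|x_i| + |y_i|).  A pair with
    x_i = y_i = 0 is perfect agreement and contributes 0.
    """
    if p.n == 0:
        raise AgreementError("SMAPE of empty input")
    num = np.abs(p.x - p.y)
    den = np.abs(p.x) + np.abs(p.y)
    terms = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(100.0 * terms.mean())


def sad(p: PairedMeasures) -> float:
    """Standardized absolute difference: mean |d| over the pooled scale.

    SAD = mean(|x_i − y_i|) / sqrt((s²_x + s²_y)/2) with sample variances;
    directionless and unitless, so comparable across measures with different
    units and ranges.
    """
    if p.n < 2:
        raise AgreementError(f"SAD requires n >= 2, got n={p.n}")
    pooled = (p.s2_x + p.s2_y) / 2.0
    if pooled <= 0:
        raise AgreementError("SAD undefined: zero pooled variance")
    return float(np.mean(np.abs(p.d)) / math.sqrt(pooled))


def pearson(p: PairedMeasures) -> float:
    """Sample Pearson correlation between reference and test values."""
    if p.n < 3:
        raise AgreementError(f"Pearson correlation requires n >= 3, got n={p.n}")
    if np.ptp(p.x) == 0 or np.ptp(p.y) == 0:
        raise AgreementError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(p.x, p.y).statistic)


def icc_consistency(p: PairedMeasures) -> float:
    """Single-measure consistency ICC for two raters under a two-way model.

    Computed from the two-way ANOVA mean squares with participants as rows
    and the two devices as columns:

        ICC = (MS_rows − MS_error) / (MS_rows + (k−1)·MS_error),  k = 2.

    Consistency ignores a fixed offset between devices (the column effect);
    negative values are possible and reported as-is.
    """
    if p.n < 3:
        raise AgreementError(f"ICC requires n >= 3, got n={p.n}")
    data = np.column_stack([p.x, p.y])  # n rows, k=2 columns
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err
    if denom == 0:
        raise AgreementError("ICC undefined: zero total variance")
    return float((ms_rows - ms_err) / denom)


def cohen_d_paired(p: PairedMeasures) -> float:
    """Standardized difference of paired measurements: bias / SD(differences)."""
    if p.n < 2:
        raise AgreementError(f"paired Cohen's d requires n >= 2, got n={p.n}")
    d = p.d
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise AgreementError("paired Cohen's d undefined: zero SD of differences")
    return float(np.mean(d) / sd)


def cohen_d_two_sample(a, b) -> float:
    """Two-sample Cohen's d with the pooled SD.

    d = (mean(a) − mean(b)) / s_p,
    s_p = sqrt(((n_a−1)s²_a + (n_b−1)s²_b) / (n_a + n_b − 2)).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AgreementError("two-sample Cohen's d requires >= 2 values per group")
    return cohen_d_from_moments(
        len(a), float(a.mean()), float(a.std(ddof=1)),
        len(b), float(b.mean()), float(b.std(ddof=1)),
    )


def cohen_d_from_moments(
    n_a: int, mean_a: float, sd_a: float, n_b: int, mean_b: float, sd_b: float
) -> float:
    """Two-sample Cohen's d from printed group summaries (n, mean, SD)."""
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
    if sp2 <= 0:
        raise AgreementError("two-sample Cohen's d undefined: zero pooled SD")
    return (mean_a - mean_b) / math.sqrt(sp2)


def normality_check(p: PairedMeasures) -> tuple[float, float, bool]:
    """Shapiro-Wilk test on the differences; flag = p < 0.05 (report-only).

    The flag is informational: downstream agreement statistics are reported
    unchanged regardless of normality, with deviations attributed to sample
    size and outliers at reporting level.
    """
    if not (3 <= p.n <= 5000):
        raise AgreementError(f"Shapiro-Wilk supported for 3 <= n <= 5000, got n={p.n}")
    if np.ptp(p.d) == 0:
        raise AgreementError("Shapiro-Wilk undefined for constant differences")
    res = stats.shapiro(p.d)
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < 0.05)


def classify_magnitude(v: float) -> str:
    """Effect-size magnitude class on |v|: negligible/small/moderate/large.

    Bands: |v| < 0.1 negligible; [0.1, 0.3) small; [0.3, 0.5) moderate;
    >= 0.5 large.
    """
    if not math.isfinite(v):
        raise AgreementError(f"cannot classify non-finite value {v!r}")
    a = abs(v)
    if a < 0.1:
        return "negligible"
    if a < 0.3:
        return "small"
    if a < 0.5:
        return "moderate"
    return "large"


def is_satisfactory_summary(measure_name: str, icc: float) -> bool:
    """Whether a summary-measure ICC clears its inter-scorer threshold (strict >)."""
    if measure_name not in SUMMARY_ICC_THRESHOLDS:
        raise AgreementError(f"no satisfactory-agreement threshold for measure {measure_name!r}")
    return icc > SUMMARY_ICC_THRESHOLDS[measure_name]


def normal_ci(mean: float, sd: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% CI of a mean: mean ± 1.96·SD/√n."""
    if n < 2:
        raise AgreementError("CI requires n >= 2")
    half = 1.96 * sd / math.sqrt(n)
    return (mean - half, mean + half)


def compute_agreement(p: PairedMeasures) -> AgreementReport:
    """Full agreement panel for one measure; undefined entries become NaN."""
    ba = bland_altman(p)
    def _try(fn, *args):
        try:
            return fn(*args)
        except AgreementError:
            return float("nan")

    rho = _try(pearson, p)
    icc = _try(icc_consistency, p)
    d = _try(cohen_d_paired, p)
    sm = _try(smape, p)
    sa = _try(sad, p)
    try:
        w, pv, flag = normality_check(p)
    except AgreementError:
        w, pv, flag = float("nan"), float("nan"), False
    try:
        satisf: bool | None = is_satisfactory_summary(p.measure_name, icc)
    except AgreementError:
        satisf = None
    return AgreementReport(
        measure_name=p.measure_name, n=p.n,
        bias=ba.bias, sd_diff=ba.sd_diff, loa_low=ba.loa_low, loa_high=ba.loa_high,
        ci_bias=ba.ci_bias, ci_loa_low=ba.ci_loa_low, ci_loa_high=ba.ci_loa_high,
        mdc=ba.mdc, rho=rho, icc=icc, cohen_d=d, smape=sm, sad=sa,
        normality_w=w, normality_p=pv, non_normal=flag, satisfactory=satisf,
    )
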