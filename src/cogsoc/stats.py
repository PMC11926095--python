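"""Nonparametric hypothesis-testing toolkit.

The dependent variables in this pipeline (membership coefficients, Jaccard
indices, correlations) are not normally distributed, so group comparisons
use the two-sided Mann-Whitney U test with the Hodges-Lehmann estimator
(median of all pairwise differences) as the shift effect size, Spearman rank
correlation for continuous predictors, and a Shapiro-Wilk gate to verify the
nonparametric route. The type I error level is 0.05 throughout and no
multiple-testing correction is applied; every reported p-value is a
per-comparison value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ALPHA",
    "TestResult",
    "mann_whitney_two_sided",
    "hodges_lehmann",
    "spearman_correlation",
    "normality_gate",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """A test statistic with p-value and Hodges-Lehmann effect size + 95% CI."""

    statistic: float
    p_value: float
    effect_size: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n1: int = 0
    n2: int = 0


def hodges_lehmann(x, y, alpha: float = ALPHA) -> tuple[float, float, float]:
    """Hodges-Lehmann shift estimate with a distribution-free CI.

    The estimate is the median of all m*n pairwise differences x_i - y_j.
    The confidence interval takes the order statistics of the
    pairwise-difference set at the ranks matching the two-sided
    Mann-Whitney critical value at level ``alpha`` (normal approximation to
    the rank, the classical companion interval to the estimator).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    est = float(np.median(diffs))
    m, n = x.size, y.size
    mn = m * n
    z = sps.norm.ppf(1 - alpha / 2)
    k = int(np.floor(mn / 2 - z * np.sqrt(mn * (m + n + 1) / 12.0)))
    if k < 1:
        # too few pairs for the nominal level; widest available interval
        return est, float(diffs[0]), float(diffs[-1])
    return est, float(diffs[k - 1]), float(diffs[mn - k])


def mann_whitney_two_sided(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test of a location shift between two samples.

    Exact enumeration is used for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's ``method="auto"``
    switch). The Hodges-Lehmann shift estimate and its 95% CI accompany the
    U statistic (U counts x-over-y pairs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    est, lo, hi = hodges_lehmann(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=est,
        ci_low=lo,
        ci_high=hi,
        n1=int(x.size),
        n2=int(y.size),
    )


def spearman_correlation(a, b) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with p-value.

    Returns (NaN, NaN) with a warning when either input is constant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("inputs must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant input; Spearman correlation undefined", stacklevel=2)
        return (np.nan, np.nan)
    rho, p = sps.spearmanr(a, b)
    return (float(rho), float(p))


def normality_gate(sample, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk normality verdict at level ``alpha``.

    True means "compatible with normal" (p > alpha); the pipeline routes to
    nonparametric tests whenever this returns False. Constant samples are
    degenerate and reported non-normal with a warning. Sample sizes outside
    3..5000 are rejected (the test statistic is not calibrated there).
    """
    sample = np.asarray(sample, dtype=float)
    if not 3 <= sample.size <= 5000:
        raise ValueError(f"sample size {sample.size} outside the 3..5000 range")
    if np.ptp(sample) == 0:
        warnings.warn("constant sample; treated as non-normal", stacklevel=2)
        return False
    _, p = sps.shapiro(sample)
    return bool(p > alpha)
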