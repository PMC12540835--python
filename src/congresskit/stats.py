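"""Group-comparison statistics for congression events and intensities.

The battery: one-way ANOVA with two-sided Tukey HSD post-hoc comparisons
(Tukey-Kramer for unequal group sizes) for multi-class continuous outcomes
such as congression velocities; pooled two-tailed two-proportion z-tests and
a chi-square test of independence for alignment-success proportions and
category tables (no continuity correction); ordinary least squares with a
two-tailed t-test on the slope and R-squared for intensity-kinematics
couplings; and mean +/- s.d. summaries with t-based and chi-square-based 95%
confidence intervals for the mean and the s.d. respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .errors import UndefinedDenominatorError


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares fit of y on x."""

    slope: float
    intercept: float
    r_squared: float
    p_slope: float  # two-tailed t-test on the slope, n - 2 df
    n: int


@dataclass(frozen=True)
class MeanSdCI:
    mean: float
    sd: float
    ci_mean: tuple[float, float]
    ci_sd: tuple[float, float]
    n: int
    degenerate: bool  # zero variance: the s.d. interval collapses


def significance_stars(p: float) -> str:
    """Display tiers: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return "n.s."


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F-test plus pairwise two-sided Tukey HSD.

    Adjusted pairwise p-values come from the studentized-range distribution
    with the Tukey-Kramer allowance for unequal group sizes.  Returns
    (F, p, table) where the table has one row per unordered pair with columns
    group1, group2, mean_diff, p_adj.
    """
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    if any(len(d) < 2 for d in data):
        raise ValueError("each group needs n >= 2 for variance-based tests")
    if np.ptp(np.concatenate(data)) == 0:
        # all observations identical: F = 0, no evidence of any difference
        rows = [
            {"group1": labels[i], "group2": labels[j], "mean_diff": 0.0, "p_adj": 1.0}
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        return 0.0, 1.0, pd.DataFrame(rows)
    F, p = sps.f_oneway(*data)
    res = sps.tukey_hsd(*data)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": float(np.mean(data[i]) - np.mean(data[j])),
                    "p_adj": float(res.pvalue[i, j]),
                }
            )
    return float(F), float(p), pd.DataFrame(rows)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-tailed two-proportion z-test with pooled variance.

    The z statistic is signed as p1 - p2.  A pooled proportion of exactly 0
    or 1 leaves the null variance undefined and raises.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 < 1 or n2 < 1:
        raise ValueError("need 0 <= k <= n and n >= 1 in both groups")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise UndefinedDenominatorError(
            "pooled proportion of 0 or 1 has zero variance under the null"
        )
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal total: expected counts undefined")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Closed-form OLS of y on x with slope t-test (n - 2 df) and R-squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.var(x) == 0:
        raise ValueError("x is constant: slope undefined")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_slope=float(fit.pvalue),
        n=int(x.size),
    )


def mean_sd_ci(values: Sequence[float], confidence: float = 0.95) -> MeanSdCI:
    """Mean and s.d. with t-based and chi-square-based confidence intervals.

    CI of the mean: xbar +/- t_{a/2, n-1} * s / sqrt(n).  CI of the s.d.:
    sqrt((n-1) s^2 / chi2_{1-a/2}) .. sqrt((n-1) s^2 / chi2_{a/2}).  Zero
    sample variance gives collapsed intervals, flagged degenerate.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("need n >= 2")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    alpha = 1.0 - confidence
    if sd == 0:
        return MeanSdCI(mean, 0.0, (mean, mean), (0.0, 0.0), n, degenerate=True)
    tcrit = sps.t.ppf(1 - alpha / 2, n - 1)
    half = tcrit * sd / np.sqrt(n)
    lo_chi = sps.chi2.ppf(alpha / 2, n - 1)
    hi_chi = sps.chi2.ppf(1 - alpha / 2, n - 1)
    ci_sd = (
        float(np.sqrt((n - 1) * sd**2 / hi_chi)),
        float(np.sqrt((n - 1) * sd**2 / lo_chi)),
    )
    return MeanSdCI(mean, sd, (mean - half, mean + half), ci_sd, n, degenerate=False)
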