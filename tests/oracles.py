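"""Independent oracles used by the test suite.

These deliberately avoid the implementation paths they check: plane distance
by dense sampling of the plane, sums-of-squares ANOVA, normal-equations OLS,
pooled-z and expected-count formulas written out longhand.
"""

import math

import numpy as np


def brute_force_plane_distance(p, midpoint, axis, half_extent=25.0):
    """Min distance from p to the plane through `midpoint` normal to `axis`,
    by coarse-to-fine dense sampling of plane points (no projection formula).
    """
    axis = np.asarray(axis, float)
    p = np.asarray(p, float)
    e1 = np.array([axis[1], -axis[0], 0.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.array([0.0, axis[2], -axis[1]])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    def scan(center, extent, step):
        s = np.arange(-extent, extent + step / 2, step)
        pts = (
            np.asarray(midpoint, float)
            + center[0] * e1
            + center[1] * e2
            + s[:, None, None] * e1
            + s[None, :, None] * e2
        )
        d2 = ((pts - p) ** 2).sum(-1)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        return np.sqrt(d2[i, j]), (center[0] + s[i], center[1] + s[j])

    _, best = scan((0.0, 0.0), half_extent, 0.25)
    d, _ = scan(best, 0.3, 0.001)
    return float(d)


def anova_sums_of_squares(groups):
    """Textbook one-way ANOVA decomposition: returns (F, df_between, df_within)."""
    all_vals = [x for g in groups for x in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(
        sum((x - sum(g) / len(g)) ** 2 for x in g) for g in groups
    )
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


def normal_equations_ols(x, y):
    """Slope and intercept from the 2x2 normal equations, solved longhand."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx, sxy = sum(v * v for v in x), sum(a * b for a, b in zip(x, y))
    det = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / det
    intercept = (sxx * sy - sx * sxy) / det
    return slope, intercept


def pooled_z(k1, n1, k2, n2):
    """Two-proportion pooled z statistic computed longhand."""
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return (p1 - p2) / se


def chi_square_expected_counts(table):
    """Pearson chi-square via explicit expected-count loops."""
    table = np.asarray(table, float)
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    total = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            exp = row[i] * col[j] / total
            chi2 += (table[i, j] - exp) ** 2 / exp
    return chi2
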