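"""Validation statistics for motion-accuracy studies.

Two-sample comparisons of DTW distance distributions (Student/Welch t,
Mann-Whitney U with normal approximation), ordinal rater agreement
(Kendall tau-b), independence of recognizer error counts (Pearson
chi-square) and an equality-of-variances screen (Levene).  Summary-based
entry points accept the n/mean/SD or rank-sum values that published
tables print, so reported statistics can be recomputed without raw data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "students_t",
    "students_t_raw",
    "mann_whitney",
    "mann_whitney_from_ranks",
    "kendall_tau_b",
    "pearson_chi_square",
    "levene_test",
]


@dataclass
class StatResult:
    """A test statistic with its degrees of freedom and two-tailed p-value."""

    statistic: float
    df: float | None
    p_value: float
    method: str
    z: float | None = None  # normal-approximation Z, where applicable
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")
        if self.df is not None and self.df <= 0:
            raise ValueError("df must be positive when present")


# ---------------------------------------------------------------------------
# t tests


def students_t(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, equal_var: bool = True
) -> StatResult:
    """Independent two-sample t test from group summaries.

    ``equal_var=True`` pools the variances (df = n1 + n2 - 2);
    ``equal_var=False`` is Welch's test with Satterthwaite df.  Sign
    convention: group 1 minus group 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            df = n1 + n2 - 2
            return StatResult(0.0, float(df), 1.0, "t" if equal_var else "welch")
        raise ValueError("zero variance with unequal means: statistic is infinite")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
        method = "t"
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        method = "welch"
    return StatResult(float(t), df, float(p), method)


def students_t_raw(x, y, equal_var: bool = True) -> StatResult:
    """Independent two-sample t test on raw observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return students_t(
        len(x), x.mean(), x.std(ddof=1), len(y), y.mean(), y.std(ddof=1), equal_var=equal_var
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mwu_from_u1(n1: int, n2: int, u1: float, tie_term: float = 0.0) -> StatResult:
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    mu = n1 * n2 / 2.0
    N = n1 + n2
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (u - mu) / math.sqrt(var)  # no continuity correction
        p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(float(u), None, float(min(1.0, p)), "mann-whitney", z=float(z))


def mann_whitney(x, y) -> StatResult:
    """Mann-Whitney U with normal-approximation Z (tie-corrected).

    U = min(U1, U2) where U1 = R1 - n1(n1+1)/2; Z uses the tie-corrected
    variance and no continuity correction; p is two-tailed normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    return _mwu_from_u1(n1, n2, u1, tie_term)


def mann_whitney_from_ranks(n1: int, n2: int, rank_sum1: float) -> StatResult:
    """Mann-Whitney U and Z from printed group sizes and a rank sum.

    Assumes no ties (published rank-sum tables carry no tie information).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    u1 = rank_sum1 - n1 * (n1 + 1) / 2.0
    if not 0 <= u1 <= n1 * n2:
        raise ValueError("rank sum incompatible with the group sizes")
    return _mwu_from_u1(n1, n2, u1)


# ---------------------------------------------------------------------------
# agreement / independence


def kendall_tau_b(x, y) -> StatResult:
    """Kendall tau-b rank correlation (tie-corrected), for ordinal data."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("samples must have equal length >= 2")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("tau-b is undefined when either vector is constant")
    res = sps.kendalltau(x, y, variant="b")
    return StatResult(float(res.statistic), None, float(res.pvalue), "kendall-tau-b")


def pearson_chi_square(table) -> StatResult:
    """Pearson chi-square test of independence on a counts table.

    df = (rows - 1)(cols - 1); expected counts from the marginals.  The
    result is flagged ``low_expected_count`` when any expected cell is
    below 5 (the usual validity caution for the asymptotic test).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("every row and column must have a positive total")
    res = sps.chi2_contingency(table, correction=False)
    flags = ("low_expected_count",) if np.any(res.expected_freq < 5) else ()
    return StatResult(
        float(res.statistic), float(res.dof), float(res.pvalue), "pearson-chi2", flags=flags
    )


def levene_test(x, y) -> StatResult:
    """Levene's equality-of-variances test (mean-centered deviations)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    stat, p = sps.levene(x, y, center="mean")
    return StatResult(float(stat), float(len(x) + len(y) - 2), float(p), "levene")
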