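"""Nonparametric statistics kit used across the cohort analyses.

Thin, policy-carrying wrappers around scipy.stats / statsmodels: two-sided
tests throughout; Wilcoxon signed-rank drops zero differences (Wilcoxon's
convention) and uses the exact null for n <= 25 without ties; FDR correction
is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "shapiro_wilk",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "spearman",
    "fisher_exact",
    "fdr_bh",
]

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str = ""
    n: int = 0


def shapiro_wilk(values) -> TestResult:
    values = np.asarray(values, float)
    stat, p = scipy.stats.shapiro(values)
    return TestResult(float(stat), float(p), "shapiro-wilk", values.size)


def _has_ties(v: np.ndarray) -> bool:
    return np.unique(v).size < v.size


def wilcoxon_signed_rank(a, b=None) -> TestResult:
    """Paired two-sided Wilcoxon signed-rank test.

    ``a`` may be the paired differences directly, or paired with ``b``.
    Zero differences are dropped; all-zero differences give p = 1 with a
    warning.  Exact null distribution for n <= 25 without ties, otherwise
    normal approximation with continuity correction.
    """
    d = np.asarray(a, float) - (0.0 if b is None else np.asarray(b, float))
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p-value defined as 1")
        return TestResult(0.0, 1.0, "signed-rank (degenerate)", 0)
    if d.size <= _EXACT_N_MAX and not _has_ties(np.abs(d)):
        method = "exact"
    else:
        method = "approx"
    stat, p = scipy.stats.wilcoxon(
        d, alternative="two-sided", method=method, correction=(method == "approx"),
        zero_method="wilcox",
    )
    return TestResult(float(stat), float(p), f"signed-rank ({method})", d.size)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    small = max(x.size, y.size) <= _EXACT_N_MAX
    exact = small and not _has_ties(np.concatenate([x, y]))
    stat, p = scipy.stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic",
        use_continuity=not exact,
    )
    return TestResult(float(stat), float(p), f"rank-sum ({'exact' if exact else 'asymptotic'})",
                      x.size + y.size)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant input: Spearman rho undefined")
        return TestResult(float("nan"), float("nan"), "spearman (degenerate)", x.size)
    rho, p = scipy.stats.spearmanr(x, y)
    return TestResult(float(rho), float(p), "spearman", x.size)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table of nonnegative integers."""
    table = np.asarray(table)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("Fisher exact test needs a nonnegative 2x2 table")
    odds, p = scipy.stats.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), "fisher-exact", int(table.sum()))


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, never below raw p)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p.copy()
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return adj
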