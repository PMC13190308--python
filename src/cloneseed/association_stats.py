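"""Contingency and correlation statistics with pinned-down conventions.

The conventions matter for reproducing printed p-values: the two-sided
Fisher test uses the standard small-p criterion (sum of hypergeometric
probabilities no larger than the observed table's), the chi-squared test
applies the Yates continuity correction on 2x2 tables by default, rank
tests use exact null distributions at small n, and Pearson correlation
carries the usual t-distributed p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _coerce(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        return table.as_array()
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return arr


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p-value (small-p criterion)."""
    return float(stats.fisher_exact(_coerce(table)).pvalue)


def chi_squared(table, yates: bool = True) -> float:
    """Pearson chi-squared p-value on a 2x2 table, Yates-corrected by
    default; NaN when an expected cell is zero."""
    arr = _coerce(table)
    expected = stats.contingency.expected_freq(arr)
    if (expected == 0).any():
        return math.nan
    return float(stats.chi2_contingency(arr, correction=yates).pvalue)


def rank_tests(x, y, paired: bool = False) -> float:
    """Two-sided rank test: Wilcoxon signed-rank when paired, otherwise
    Mann-Whitney U.  Exact null distributions are used for n <= 25 without
    ties; all-tied paired differences return NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal lengths")
        diffs = x - y
        if np.all(diffs == 0):
            return math.nan
        mode = "exact" if len(x) <= 25 and not _has_tied_diffs(diffs) else "approx"
        return float(stats.wilcoxon(x, y, mode=mode).pvalue)
    method = "exact" if (len(x) <= 25 and len(y) <= 25
                         and not _has_cross_ties(x, y)) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, method=method).pvalue)


def _has_tied_diffs(diffs: np.ndarray) -> bool:
    nz = np.abs(diffs[diffs != 0])
    return len(np.unique(nz)) < len(nz) or (diffs == 0).any()


def _has_cross_ties(x: np.ndarray, y: np.ndarray) -> bool:
    joined = np.concatenate([x, y])
    return len(np.unique(joined)) < len(joined)


def correlation_report(
    x, y, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation coefficient and p-value; (NaN, NaN) for degenerate
    input (fewer than three pairs or zero variance)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired vectors required")
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def fisher_exact_enumerated(table) -> float:
    """Independent small-p Fisher implementation by full enumeration of the
    hypergeometric support; an oracle for cross-checking on small tables."""
    arr = _coerce(table)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    probs = {
        k: stats.hypergeom.pmf(k, n, col1, row1) for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9)))
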