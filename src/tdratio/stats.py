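"""Nonparametric tests and multiplicity control used throughout the pipeline.

Paired comparisons use the Wilcoxon signed-rank test (exact sign-vector
enumeration for n <= 25 without tied magnitudes, otherwise midranks with a
continuity-corrected normal approximation); unpaired comparisons use the
Wilcoxon rank-sum test (exact for small tie-free groups).  Multiple testing
is controlled with Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_SIGNED_RANK_MAX_N = 25
EXACT_RANK_SUM_MAX_N = 10


@dataclass
class TestResult:
    statistic: float
    p: float
    alternative: str
    method: str
    n: int


def wilcoxon_signed_rank(x, y=None, alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test on paired data (or a difference vector).

    Zero differences are dropped with a warning.  For n <= 25 tie-free
    magnitudes the p-value is from the exact distribution over all 2^n sign
    assignments; otherwise midranks with a continuity-corrected normal
    approximation are used.
    """
    x = np.asarray(x, dtype=float)
    diffs = x - np.asarray(y, dtype=float) if y is not None else x
    nonzero = diffs[diffs != 0]
    n_dropped = len(diffs) - len(nonzero)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} zero difference(s)")
    if len(nonzero) == 0:
        raise ValueError("all differences are zero")
    ties = len(np.unique(np.abs(nonzero))) < len(nonzero)
    exact = len(nonzero) <= EXACT_SIGNED_RANK_MAX_N and not ties
    res = sps.wilcoxon(nonzero, alternative=alternative,
                       method="exact" if exact else "approx",
                       correction=not exact)
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      alternative=alternative,
                      method="signed_rank_exact" if exact else "signed_rank_normal",
                      n=len(nonzero))


def wilcoxon_rank_sum(x, y, alternative: str = "greater") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two independent groups."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = min(len(x), len(y)) <= EXACT_RANK_SUM_MAX_N and not ties
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if exact else "asymptotic")
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      alternative=alternative,
                      method="rank_sum_exact" if exact else "rank_sum_normal",
                      n=len(x) + len(y))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
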