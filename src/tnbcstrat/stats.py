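"""Exact and rank-based tests used across the pipeline.

Standard tests delegate to scipy/statsmodels; the r x c Fisher exact test
(Freeman-Halton) is implemented here by direct enumeration over tables
with fixed margins, since no installed library provides it. The 2x2 case
is served by the hypergeometric formulation (scipy) and agrees with the
general enumeration to floating-point precision.
"""

from __future__ import annotations

from functools import lru_cache
from math import lgamma
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: relative tolerance for "probability <= observed" in two-sided Fisher tests
FISHER_REL_TOL = 1e-7

#: largest grand total enumerated exactly beyond 2x2
RXC_ENUMERATION_BOUND = 500


def _as_table(t) -> np.ndarray:
    arr = np.asarray(t.values if isinstance(t, pd.DataFrame) else t)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(arr < 0):
        raise ValueError("contingency table entries must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table entries must be integers")
    return arr.astype(np.int64)


def fisher_exact(t) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    2x2 tables use the hypergeometric formulation; larger tables use the
    Freeman-Halton generalization by full enumeration over tables with the
    observed margins (grand total capped at 500 — use :func:`chi_square`
    beyond that). Two-sided p sums the probabilities of tables no more
    probable than the observed one.
    """
    arr = _as_table(t)
    if arr.shape == (2, 2):
        return float(sps.fisher_exact(arr, alternative="two-sided")[1])
    if arr.sum() > RXC_ENUMERATION_BOUND:
        raise ValueError(
            f"grand total {arr.sum()} exceeds the exact enumeration bound "
            f"({RXC_ENUMERATION_BOUND}); consider chi_square instead"
        )
    return fisher_exact_rxc(arr)


def _log_table_prob(arr: np.ndarray, log_const: float) -> float:
    return log_const - sum(lgamma(v + 1.0) for v in arr.ravel())


def fisher_exact_rxc(t) -> float:
    """Freeman-Halton exact test by enumeration over fixed-margin tables."""
    arr = _as_table(t)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = arr.sum()
    if n == 0:
        raise ValueError("empty contingency table")
    log_const = (
        sum(lgamma(r + 1.0) for r in rows)
        + sum(lgamma(c + 1.0) for c in cols)
        - lgamma(n + 1.0)
    )
    obs_logp = _log_table_prob(arr, log_const)
    cutoff = obs_logp + np.log1p(FISHER_REL_TOL)
    nrow = len(rows)

    total = 0.0

    def fill_row(i: int, remaining_cols: tuple, acc_neg_lgamma: float) -> None:
        nonlocal total
        if i == nrow - 1:
            # last row is forced by the column margins
            logp = (
                log_const + acc_neg_lgamma
                - sum(lgamma(c + 1.0) for c in remaining_cols)
            )
            if logp <= cutoff:
                total += np.exp(logp)
            return
        for comp in _compositions(int(rows[i]), remaining_cols):
            neg = acc_neg_lgamma - sum(lgamma(v + 1.0) for v in comp)
            fill_row(
                i + 1,
                tuple(rc - v for rc, v in zip(remaining_cols, comp)),
                neg,
            )

    fill_row(0, tuple(int(c) for c in cols), 0.0)
    return float(min(1.0, total))


def _compositions(total: int, caps: Sequence[int]):
    """All ways to split ``total`` over cells bounded by ``caps``."""
    if len(caps) == 1:
        if total <= caps[0]:
            yield (total,)
        return
    tail_cap = sum(caps[1:])
    lo = max(0, total - tail_cap)
    hi = min(caps[0], total)
    for v in range(lo, hi + 1):
        for rest in _compositions(total - v, caps[1:]):
            yield (v,) + rest


def chi_square(t):
    """Pearson chi-square on a contingency table.

    Returns ``(statistic, p, df, expected)`` without continuity correction.
    A zero row or column margin is an error.
    """
    arr = _as_table(t)
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("zero margin in contingency table")
    stat, p, df, expected = sps.chi2_contingency(arr, correction=False)
    return float(stat), float(p), int(df), expected


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode="exact"`` enumerates the null distribution (valid for untied
    data); ``mode="normal_approx"`` uses the tie-corrected normal
    approximation with continuity correction; ``mode="auto"`` picks exact
    when the combined size is <= 20 and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 20 and not has_ties) else "normal_approx"
    if mode == "exact":
        method = "exact"
    elif mode == "normal_approx":
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson on mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    return float(sps.spearmanr(x, y).statistic)
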