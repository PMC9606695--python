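"""Shared statistical primitives: vectorized Fisher's exact test, BH-FDR,
and the Wilcoxon rank-sum wrapper used across modules.

The two-sided Fisher test is implemented here (rather than looping over
``scipy.stats.fisher_exact``) because DMR calling evaluates it on up to ~10^5
tiles per context; the hypergeometric pmf is computed from log-gamma terms over
the full support of every table in one flat vectorized pass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

# Relative gate for two-sided tail accumulation: probabilities within a factor
# (1 + 1e-7) of the observed pmf count as "at least as extreme".  This is the
# convention used by R's fisher.test and scipy.
_GATE = 1.0 + 1e-7


def _log_binom(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_two_sided(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher's exact p-values for 2x2 tables [[a, b], [c, d]].

    Parameters are array-like of non-negative integers (broadcast to 1-D).
    Returns an array of p-values; p = sum over the hypergeometric support of
    every pmf value not exceeding the observed one (with the standard relative
    tolerance for ties).
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("negative counts in 2x2 table")

    n_row1 = a + b
    n_col1 = a + c
    total = a + b + c + d

    kmin = np.maximum(0, n_col1 - (total - n_row1))
    kmax = np.minimum(n_col1, n_row1)
    support = (kmax - kmin + 1).astype(np.int64)

    starts = np.cumsum(support) - support
    flat_n = int(support.sum())
    table_idx = np.repeat(np.arange(a.size), support)
    ks = np.arange(flat_n) - np.repeat(starts, support) + np.repeat(kmin, support)

    log_denom = _log_binom(total, n_row1)
    log_pmf = (
        _log_binom(n_col1[table_idx], ks)
        + _log_binom((total - n_col1)[table_idx], n_row1[table_idx] - ks)
        - log_denom[table_idx]
    )
    log_obs = (
        _log_binom(n_col1, a)
        + _log_binom(total - n_col1, n_row1 - a)
        - log_denom
    )

    extreme = log_pmf <= log_obs[table_idx] + np.log(_GATE)
    contrib = np.where(extreme, np.exp(log_pmf), 0.0)
    p = np.add.reduceat(contrib, starts)
    # tables with empty margins have a single support point -> p exactly 1
    return np.minimum(p, 1.0)


def fisher_exact_scalar(a: int, b: int, c: int, d: int) -> float:
    return float(fisher_exact_two_sided([a], [b], [c], [d])[0])


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y, exact_max: int = 20) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration for small samples (both sizes <= ``exact_max`` and
    no ties); normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample in rank-sum test")
    n_all = np.concatenate([x, y])
    has_ties = np.unique(n_all).size < n_all.size
    if max(x.size, y.size) <= exact_max and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
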