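"""Shared statistical engines.

Three primitives are used throughout the pipeline: the paired Wilcoxon
signed-rank test (differential splicing and differential expression),
Benjamini-Hochberg step-up FDR adjustment, and Spearman rank correlation.
They are collected here so that every stage tests and corrects with the
same conventions.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = ["paired_wilcoxon", "bh_fdr", "spearman"]

#: sample size at or below which the exact signed-rank null is used
EXACT_WILCOXON_MAX_N = 25

#: sample size at or below which the exact permutation null is used for Spearman
EXACT_SPEARMAN_MAX_N = 7


def _exact_signed_rank_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact two-sided p over the 2^n equally likely sign assignments.

    Computed by dynamic programming on the distribution of W+ (ranks are
    doubled so that average ranks from ties become integers); equivalent
    to full enumeration. The null distribution is symmetric around
    n(n+1)/4, so the two-sided p is the probability of a W+ at least as
    far from the center as observed.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[:total + 1 - r]
    center = total / 2.0
    dev = abs(2.0 * w_pos - center)
    support = np.arange(total + 1)
    mask = np.abs(support - center) >= dev - 1e-9
    return float(counts[mask].sum() / 2.0 ** len(r2))


def paired_wilcoxon(differences: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped before ranking; tied absolute differences
    receive average ranks. The p-value comes from the exact signed-rank
    null distribution (equivalent to enumerating all ``2^n`` sign
    assignments, with tied ranks handled exactly) when the post-drop
    sample size is at most ``EXACT_WILCOXON_MAX_N``; otherwise the normal
    approximation with tie and continuity correction is used. If every
    difference is zero the test carries no signal and ``p = 1``.

    Parameters
    ----------
    differences
        Non-empty 1-D vector of paired differences.

    Returns
    -------
    (statistic, p)
        ``statistic`` is W+, the sum of ranks of the positive differences;
        ``p`` is the two-sided p-value in ``(0, 1]``.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("paired_wilcoxon requires a non-empty 1-D vector")
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = _sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_signed_rank_p(ranks, w_pos)
    else:
        res = _sps.wilcoxon(d, zero_method="wilcox", correction=True,
                            method="approx")
        p = float(res.pvalue)
    return w_pos, min(p, 1.0)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    ``q[i] = min_{j: p[j] >= p[i]} p[j] * m / rank(p[j])`` clipped to 1,
    returned in the input order.

    Raises
    ------
    ValueError
        If any p-value lies outside ``(0, 1]``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_fdr expects a 1-D vector of p-values")
    if p.size == 0:
        return np.empty(0)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _rank_corr(rx_c: np.ndarray, ry_c: np.ndarray, nx: float, ny: float) -> float:
    return float(np.dot(rx_c, ry_c) / (nx * ny))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a small-sample exact p-value.

    Both vectors are converted to average ranks; rho is the Pearson
    correlation of the ranks. For ``n <= EXACT_SPEARMAN_MAX_N`` the p-value
    is exact, by enumerating all ``n!`` permutations of one rank vector;
    for larger ``n`` the usual t approximation with ``n - 2`` degrees of
    freedom is used.

    Returns ``(nan, nan)`` when either vector has zero variance (rho is
    undefined and the caller should treat the result as absent).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("spearman requires two equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires at least 3 observations")
    if x.max() == x.min() or y.max() == y.min():
        return math.nan, math.nan
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    nx = float(np.linalg.norm(rx_c))
    ny = float(np.linalg.norm(ry_c))
    rho = _rank_corr(rx_c, ry_c, nx, ny)
    if n <= EXACT_SPEARMAN_MAX_N:
        threshold = abs(rho) - 1e-12
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _rank_corr(rx_c, ry_c[list(perm)], nx, ny)
            hits += abs(r) >= threshold
            total += 1
        p = hits / total
    else:
        r = min(max(rho, -1.0), 1.0)
        if 1.0 - r * r <= 0.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    # p stays strictly positive so downstream FDR adjustment accepts it
    return rho, min(max(p, float(np.finfo(float).tiny)), 1.0)
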