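"""Internal vectorized statistics: signed-rank p-values and run finding.

The per-bin preference machinery evaluates a Wilcoxon signed-rank test on
grids of (iteration x bin) difference vectors; scipy's implementation is
scalar-per-call and far too slow there, so the statistic and its null
distribution are computed here in vectorized form. For n <= 25 pairs the
exact (no-tie) null distribution of W+ is used; beyond that, the normal
approximation with tie correction and continuity correction. Zero
differences are handled by rank-splitting (scipy's ``zero_method="zsplit"``).
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Tuple

import numpy as np
from scipy.stats import norm, rankdata

__all__ = ["signed_rank_p", "find_runs", "pearson_rows"]

_EXACT_N_MAX = 25


@lru_cache(maxsize=64)
def _exact_cdf(n: int) -> np.ndarray:
    """CDF of W+ under H0 for n untied pairs (support 0..n(n+1)/2)."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for k in range(1, n + 1):
        counts[k:] += counts[:-k].copy()
    pmf = counts / counts.sum()
    return np.cumsum(pmf)


def signed_rank_p(d: np.ndarray, axis: int = -1) -> np.ndarray:
    """Two-sided Wilcoxon signed-rank p-values along ``axis``.

    Vectorized over all other axes. Exact null distribution for
    n <= 25 pairs (ties/zeros then handled approximately by splitting),
    normal approximation with tie and continuity corrections otherwise.
    All-zero difference vectors get p = 1.
    """
    d = np.moveaxis(np.asarray(d, dtype=float), axis, -1)
    n = d.shape[-1]
    if n < 2:
        raise ValueError("need >= 2 pairs for a signed-rank test")
    r = rankdata(np.abs(d), method="average", axis=-1)
    w_plus = np.sum(r * (d > 0), axis=-1) + 0.5 * np.sum(r * (d == 0), axis=-1)
    m = n * (n + 1) / 2.0
    if n <= _EXACT_N_MAX:
        cdf = _exact_cdf(n)
        idx_lo = np.clip(np.floor(w_plus).astype(int), 0, int(m))
        idx_hi = np.clip(np.ceil(w_plus).astype(int), 0, int(m))
        p_le = 0.5 * (cdf[idx_lo] + cdf[idx_hi])
        # P(W >= w) via symmetry of the null distribution around m/2
        idx_lo2 = np.clip(np.floor(m - w_plus).astype(int), 0, int(m))
        idx_hi2 = np.clip(np.ceil(m - w_plus).astype(int), 0, int(m))
        p_ge = 0.5 * (cdf[idx_lo2] + cdf[idx_hi2])
        p = 2.0 * np.minimum(p_le, p_ge)
    else:
        mu = m / 2.0
        # variance with tie correction: sum r^2 equals n(n+1)(2n+1)/6 - ties
        var = np.sum(r ** 2, axis=-1) / 4.0
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(np.maximum(var, 1e-12))
        p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, 0.0, 1.0)
    all_zero = np.all(d == 0, axis=-1)
    if np.any(all_zero):
        p = np.where(all_zero, 1.0, p)
    return p


def find_runs(mask: np.ndarray, min_len: int) -> List[Tuple[int, int]]:
    """Maximal runs of True of length >= min_len, as (start, length)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 1:
        raise ValueError("mask must be 1-D")
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_len:
                runs.append((start, i - start))
            start = None
    if start is not None and mask.size - start >= min_len:
        runs.append((start, mask.size - start))
    return runs


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two equally shaped 2-D arrays.

    Rows with zero variance in either input yield NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = np.sum(a * b, axis=-1)
    denom = np.sqrt(np.sum(a * a, axis=-1) * np.sum(b * b, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom == 0, np.nan, num / np.where(denom == 0, 1.0, denom))
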