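"""Independent brute-force oracles used to validate the fitting and scoring
routines: dense grid-search minimizers, exact binomial tail enumeration, and
exhaustive tiny-string global alignment."""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np


def grid_search_single_exp(
    t: np.ndarray,
    y: np.ndarray,
    k_lo: float,
    k_hi: float,
    n_k: int = 400,
) -> tuple[float, float, float, float]:
    """Dense grid over the rate; (a, b) solved per-k by linear least squares.

    Returns (k, a, b, rss).  Assumes the optimum is interior to the
    amplitude/offset box, which holds for the seeded instances used.
    """
    best = (math.nan, math.nan, math.nan, math.inf)
    for k in np.geomspace(k_lo, k_hi, n_k):
        X = np.column_stack([np.exp(-k * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((X @ coef - y) ** 2))
        if rss < best[3]:
            best = (float(k), float(coef[0]), float(coef[1]), rss)
    return best


def grid_search_mm(
    c: np.ndarray,
    k_obs: np.ndarray,
    sigma: np.ndarray,
    kcat_range: tuple[float, float],
    km_range: tuple[float, float],
    n: int = 400,
) -> tuple[float, float, float]:
    """Dense 2-D chi-square grid minimizer for the Michaelis-Menten model."""
    best = (math.nan, math.nan, math.inf)
    for kcat in np.geomspace(*kcat_range, n):
        for km in np.geomspace(*km_range, n):
            model = kcat * c / (km + c)
            chi2 = float(np.sum(((k_obs - model) / sigma) ** 2))
            if chi2 < best[2]:
                best = (float(kcat), float(km), chi2)
    return best


def exact_binomial_tail(count: int, n: int, p: float = 0.25) -> float:
    """P(X >= count) by direct summation of the binomial pmf."""
    total = 0.0
    for k in range(count, n + 1):
        total += math.comb(n, k) * p**k * (1 - p) ** (n - k)
    return total


def brute_force_global_alignment_score(
    a: str,
    b: str,
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Best global alignment score by exhaustive recursion with affine gaps.

    State: (i, j, last_move) where last_move distinguishes gap continuations.
    Exponential; only for strings of length <= ~8.
    """

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, last: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = gap_extend if last == "a" else gap_open
            best = max(best, -cost + rec(i + 1, j, "a"))
        if j < len(b):
            cost = gap_extend if last == "b" else gap_open
            best = max(best, -cost + rec(i, j + 1, "b"))
        return best

    return rec(0, 0, "m")


def permutation_spearman_p(
    x: np.ndarray, y: np.ndarray, rho_obs: float, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided permutation p-value for Spearman's rho."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        rho = np.corrcoef(rx, perm)[0, 1]
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
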