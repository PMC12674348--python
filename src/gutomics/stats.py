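"""Rank-based statistical primitives shared across the analysis stages.

Cliff's delta and its permutation test are the core differential statistic:
delta is the probability that a value from the first group exceeds one from
the second minus the reverse, estimated by pairwise comparison, and its
significance is assessed by relabelling group membership.  All estimators
here are tie-aware (ties contribute zero to delta, mid-ranks elsewhere).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preprocess import InputError

_EPS = 1e-12


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def cliffs_delta(x, y) -> float:
    """Cliff's delta of ``x`` versus ``y``.

    ``delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| * |y|)``; ties contribute
    zero.  Computed from pooled mid-ranks via the Mann-Whitney identity
    ``delta = 2 U / (m n) - 1``, which is algebraically equal to the pair
    count and costs O((m+n) log(m+n)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    m, n = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    u = ranks[:m].sum() - m * (m + 1) / 2.0
    return float(2.0 * u / (m * n) - 1.0)


def _delta_from_rank_subsets(ranks: np.ndarray, idx: np.ndarray, m: int, n: int) -> np.ndarray:
    """Deltas of the subsets ``idx`` (rows of selected positions) vs the rest."""
    u = ranks[idx].sum(axis=-1) - m * (m + 1) / 2.0
    return 2.0 * u / (m * n) - 1.0


def permutation_test_delta(x, y, n_perm: int = 2000, seed=0, exhaustive=None):
    """Two-sided permutation p-value with Cliff's delta as the statistic.

    Group labels are permuted and ``|delta*| >= |delta_obs|`` exceedances
    counted.  When the number of distinct relabelings C(m+n, m) does not
    exceed ``n_perm`` (and ``exhaustive`` is not explicitly False) the full
    enumeration is used and the p-value is an exact tail probability;
    otherwise ``n_perm`` Monte-Carlo draws give the add-one estimate
    ``(1 + exceedances) / (n_perm + 1)``, which is never zero.

    Returns ``(p, delta_obs)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    if n_perm < 1:
        raise InputError("n_perm must be at least 1")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    obs = cliffs_delta(x, y)
    if np.all(pooled == pooled[0]):
        return 1.0, 0.0
    ranks = _midranks(pooled)
    n_comb = math.comb(m + n, m)
    if exhaustive is None:
        exhaustive = n_comb <= n_perm
    if exhaustive:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(m + n), m)),
            dtype=np.intp, count=n_comb * m,
        ).reshape(n_comb, m)
        deltas = _delta_from_rank_subsets(ranks, idx, m, n)
        p = float(np.count_nonzero(np.abs(deltas) >= abs(obs) - _EPS)) / n_comb
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, m + n)), axis=1)[:, :m]
        deltas = _delta_from_rank_subsets(ranks, idx, m, n)
        exceed = int(np.count_nonzero(np.abs(deltas) >= abs(obs) - _EPS))
        p = (1.0 + exceed) / (n_perm + 1.0)
    return p, obs


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``mode='auto'`` uses the exact null enumeration for small tie-free
    samples (total n <= 12) and the normal approximation with tie and
    continuity corrections otherwise; ``'exact'``/``'approx'`` force a
    method.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if mode == "auto":
        method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    elif mode == "exact":
        method = "exact"
    elif mode == "approx":
        method = "asymptotic"
    else:
        raise InputError(f"unknown mode {mode!r}")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotonicity enforced)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InputError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman(x, y, n_perm: int = 10000, seed=0, exact_limit: int = 7):
    """Spearman rank correlation with a sample-size-adapted p-value.

    rho is the Pearson correlation of mid-ranks.  For n >= 10 the p-value
    uses the t approximation; for smaller n it is a permutation tail
    probability — exact enumeration of all n! orderings when n <=
    ``exact_limit``, otherwise ``n_perm`` Monte-Carlo draws with the add-one
    estimator.  Pairs with a missing value in either vector are dropped
    first (pairwise-complete).

    Returns ``(rho, p, n)``; a constant vector yields ``(nan, nan, n)`` with
    a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise InputError(f"need at least 4 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan"), n
    rx = _midranks(x)
    ry = _midranks(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if n >= 10:
        denom = max(1.0 - rho * rho, _EPS)
        t = rho * np.sqrt((n - 2) / denom)
        p = float(min(max(2.0 * sps.t.sf(abs(t), n - 2), np.finfo(float).tiny), 1.0))
    elif n <= exact_limit:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (rx * ry[perms]).mean(axis=1)
        p = float(np.count_nonzero(np.abs(rhos) >= abs(rho) - _EPS)) / len(perms)
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)
        rhos = (rx * ry[idx]).mean(axis=1)
        exceed = int(np.count_nonzero(np.abs(rhos) >= abs(rho) - _EPS))
        p = (1.0 + exceed) / (n_perm + 1.0)
    return rho, p, n
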