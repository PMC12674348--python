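"""Alpha and beta diversity: indices, distances, ordination, PERMANOVA.

Alpha indices follow the conventions of the classical ecology toolkits:
Shannon entropy in nats, Simpson as the Gini-Simpson index ``1 - sum p^2``
and evenness as Pielou's ``J = H / ln S``.  Beta diversity uses Bray-Curtis
dissimilarity for microbial profiles and the Euclidean metric on scaled
metabolite tables, ordinated by classical principal coordinate analysis.

PERMANOVA is implemented here from its sums-of-squares definition because
the pipeline additionally needs an exhaustive-enumeration mode on small
designs; the Monte-Carlo mode is cross-checked against an independent
implementation in the test suite.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .config import DISTAL, SMALL_INTESTINE
from .preprocess import AnalysisError, InputError
from .stats import _EPS, wilcoxon_rank_sum

__all__ = [
    "alpha_indices",
    "alpha_log2fc",
    "bray_curtis",
    "euclidean_distance",
    "pcoa",
    "permanova",
    "PermanovaResult",
    "distance_class_compare",
    "intra_inter_group_distances",
    "scale_metabolites",
]


# --------------------------------------------------------------------------
# alpha diversity
# --------------------------------------------------------------------------


def alpha_indices(counts: pd.DataFrame) -> pd.DataFrame:
    """Alpha-diversity indices per sample of a features x samples table.

    Returns one row per sample with richness S (features detected), Shannon
    H in nats, Gini-Simpson ``1 - sum p^2`` and Pielou evenness ``H/ln S``.
    Evenness is NaN for S <= 1 and all indices are 0/NaN for an all-zero
    sample, which is additionally flagged.
    """
    rows = []
    for sid in counts.columns:
        v = counts[sid].to_numpy(dtype=float)
        if np.any(v < 0):
            raise InputError(f"{sid}: negative counts")
        total = v.sum()
        detected = v > 0
        s = int(detected.sum())
        if total == 0:
            rows.append({"sample_id": sid, "richness": 0, "shannon": 0.0,
                         "simpson": 0.0, "evenness": np.nan, "all_zero": True})
            continue
        p = v[detected] / total
        h = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p**2).sum())
        j = h / np.log(s) if s >= 2 else np.nan
        rows.append({"sample_id": sid, "richness": s, "shannon": h,
                     "simpson": simpson, "evenness": j, "all_zero": False})
    return pd.DataFrame(rows).set_index("sample_id")


def alpha_log2fc(values: pd.Series, metadata: pd.DataFrame):
    """Per-sample log2 fold changes of MFD samples vs the matched LFD mean.

    ``values`` is an index (sample id) -> value series for one segment;
    ``metadata`` must carry ``sex`` and ``diet`` per sample id.  Within each
    sex, every MFD sample is expressed as log2(value / mean of that sex's
    LFD samples), and a two-sided Wilcoxon rank-sum p-value compares the
    diet groups.  A zero LFD mean yields NaN fold changes with a warning.

    Returns ``(log2fc, tests)``: a series over MFD samples and a per-sex
    DataFrame of Wilcoxon p-values and group sizes.
    """
    meta = metadata.loc[values.index]
    out = {}
    tests = []
    for sex in meta["sex"].unique():
        sel = meta["sex"] == sex
        lfd = values[sel & (meta["diet"] == "LFD")]
        mfd = values[sel & (meta["diet"] == "MFD")]
        if len(lfd) == 0:
            raise InputError(f"no LFD samples for sex {sex!r}")
        ref = lfd.mean()
        if ref == 0:
            warnings.warn(f"zero LFD mean for sex {sex!r}: log2FC undefined", stacklevel=2)
            fc = pd.Series(np.nan, index=mfd.index)
        else:
            with np.errstate(divide="ignore"):
                fc = np.log2(mfd / ref)
        out[sex] = fc
        p = (wilcoxon_rank_sum(mfd.to_numpy(), lfd.to_numpy())
             if len(mfd) and len(lfd) else np.nan)
        tests.append({"sex": sex, "p_wilcoxon": p, "n_lfd": len(lfd),
                      "n_mfd": len(mfd), "lfd_mean": ref})
    log2fc = pd.concat(out.values()) if out else pd.Series(dtype=float)
    return log2fc, pd.DataFrame(tests).set_index("sex")


# --------------------------------------------------------------------------
# distances
# --------------------------------------------------------------------------


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between the columns (samples).

    ``BC(x, y) = sum |x - y| / sum (x + y)``; 0 for identical profiles, 1
    for disjoint supports.  A pair of all-zero samples has an undefined
    ratio and is assigned distance 0 with a warning.
    """
    x = matrix.to_numpy(dtype=float).T
    if np.any(x < 0):
        raise InputError("Bray-Curtis requires nonnegative values")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(x, metric="braycurtis"))
    if np.any(np.isnan(d)):
        warnings.warn("all-zero sample pair: Bray-Curtis set to 0", stacklevel=2)
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, ids=list(matrix.columns))


def scale_metabolites(matrix: pd.DataFrame, scale: str = "zlog") -> pd.DataFrame:
    """Scaling policy applied to metabolite tables before Euclidean analyses.

    ``raw`` leaves concentrations untouched, ``log`` applies log(1 + c),
    ``zlog`` additionally standardises every metabolite to zero mean and
    unit variance (constant metabolites are left at zero).
    """
    if scale == "raw":
        return matrix.copy()
    logged = np.log1p(matrix)
    if scale == "log":
        return logged
    if scale == "zlog":
        mu = logged.mean(axis=1)
        sd = logged.std(axis=1, ddof=0).replace(0.0, 1.0)
        return logged.sub(mu, axis=0).div(sd, axis=0)
    raise InputError(f"unknown scale {scale!r}")


def euclidean_distance(matrix: pd.DataFrame, scale: str = "zlog") -> DistanceMatrix:
    """Euclidean distances between samples of a (scaled) metabolite table."""
    scaled = scale_metabolites(matrix, scale=scale)
    d = squareform(pdist(scaled.to_numpy(dtype=float).T, metric="euclidean"))
    return DistanceMatrix(d, ids=list(matrix.columns))


def pcoa(dm: DistanceMatrix, n_axes: int | None = None):
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Double-centers ``-D^2 / 2`` and eigendecomposes; axes are ordered by
    decreasing eigenvalue and restricted to positive eigenvalues, which are
    reported alongside any negative ones.  For a Euclidean-embeddable input
    the coordinate distances reproduce ``D`` exactly.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(dm, method="eigh")
    positive = int((res.eigvals > _EPS).sum())
    if n_axes is not None:
        if n_axes > positive:
            warnings.warn(
                f"requested {n_axes} axes but only {positive} positive eigenvalues; truncating",
                stacklevel=2,
            )
        keep = min(n_axes, res.samples.shape[1])
        res.samples = res.samples.iloc[:, :keep]
    return res


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    method: str
    grouping: str = ""


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        mask = labels == g
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * mask.sum())
    return ss


def permanova(dm: DistanceMatrix, grouping, n_permutations: int = 999,
              seed=0, exhaustive=None, grouping_name: str = "") -> PermanovaResult:
    """Permutational multivariate analysis of variance on a distance matrix.

    ``SS_total = sum_{i<j} d_ij^2 / N`` and ``SS_within`` sums, per group,
    the within-group squared distances divided by the group size; the
    pseudo-F statistic is ``(SS_between/(a-1)) / (SS_within/(N-a))``.  The
    p-value permutes group labels: exhaustively over all distinct label
    arrangements when their number does not exceed ``n_permutations``
    (exact tail probability), otherwise by Monte Carlo with the add-one
    estimator.
    """
    labels = np.asarray(grouping)
    n = len(labels)
    if n != dm.shape[0]:
        raise InputError("grouping length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    if np.any(counts < 2):
        small = groups[counts < 2]
        raise InputError(f"group(s) with fewer than 2 members: {list(small)}")
    a = len(groups)
    d2 = np.asarray(dm.data, dtype=float) ** 2
    ss_total = d2.sum() / (2.0 * n)

    def pseudo_f(ss_w: float) -> float:
        ss_b = ss_total - ss_w
        if ss_w <= 0:  # perfect within-group homogeneity
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / (a - 1)) / (ss_w / (n - a))

    ss_w_obs = _ss_within(d2, labels, groups)
    f_obs = pseudo_f(ss_w_obs)
    r2 = (ss_total - ss_w_obs) / ss_total if ss_total > 0 else 0.0

    n_arrangements = math.factorial(n)
    for c in counts:
        n_arrangements //= math.factorial(int(c))
    if exhaustive is None:
        exhaustive = n_arrangements <= n_permutations

    if exhaustive:
        # enumerate distinct multiset permutations via positions of each label
        count = 0
        exceed = 0
        for perm in _multiset_permutations(labels):
            count += 1
            if pseudo_f(_ss_within(d2, perm, groups)) >= f_obs - _EPS:
                exceed += 1
        p = exceed / count
        return PermanovaResult(float(f_obs), float(r2), float(p), count,
                               "exhaustive", grouping_name)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if pseudo_f(_ss_within(d2, perm, groups)) >= f_obs - _EPS:
            exceed += 1
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations,
                           "monte-carlo", grouping_name)


def _multiset_permutations(labels: np.ndarray):
    """Yield every distinct arrangement of a label multiset."""
    groups, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    positions = list(range(n))

    def rec(remaining, gi, current):
        if gi == len(groups) - 1:
            arr = current.copy()
            for pos in remaining:
                arr[pos] = groups[gi]
            yield arr
            return
        for combo in itertools.combinations(remaining, int(counts[gi])):
            arr = current.copy()
            for pos in combo:
                arr[pos] = groups[gi]
            rest = [p for p in remaining if p not in set(combo)]
            yield from rec(rest, gi + 1, arr)

    template = np.empty(n, dtype=groups.dtype)
    yield from rec(positions, 0, template)


# --------------------------------------------------------------------------
# distance-set comparisons
# --------------------------------------------------------------------------


def _mean_diff_permutation_p(x: np.ndarray, y: np.ndarray, n_perm: int, rng) -> float:
    """Two-sided permutation test on the difference of means."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    obs = abs(x.mean() - y.mean())
    m = len(x)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:m].mean() - perm[m:].mean()) >= obs - _EPS:
            exceed += 1
    return (1.0 + exceed) / (n_perm + 1.0)


def segment_pair_class(seg_a: str, seg_b: str) -> str:
    """Distance class of a segment pair: small/small, mixed, or distal/distal."""
    in_si = (seg_a in SMALL_INTESTINE, seg_b in SMALL_INTESTINE)
    in_distal = (seg_a in DISTAL, seg_b in DISTAL)
    if all(in_si):
        return "small_intestine"
    if all(in_distal):
        return "distal"
    if not any(in_si) or not any(in_distal):
        raise InputError(f"unknown segment label in pair ({seg_a!r}, {seg_b!r})")
    return "mixed"


def distance_class_compare(dm: DistanceMatrix, segments: pd.Series,
                           n_perm: int = 999, seed=0):
    """Inter-segment distance distributions and their pairwise comparisons.

    Every unordered segment pair contributes the set of distances between
    its samples, labelled small-intestine/mixed/distal.  Segment pairs that
    share a segment are compared by a two-sided permutation test on the
    mean distance, with Holm adjustment across comparisons.  Degenerate
    comparisons (all distances identical) are flagged with p = 1.

    Returns ``(pair_distances, comparisons)``.
    """
    segments = segments.loc[list(dm.ids)]
    segs = list(pd.unique(segments))
    for s in segs:
        segment_pair_class(s, s)  # validates labels
    d = np.asarray(dm.data)
    idx = {s: np.flatnonzero((segments == s).to_numpy()) for s in segs}

    dist_sets = {}
    rows = []
    for a, b in itertools.combinations(segs, 2):
        vals = d[np.ix_(idx[a], idx[b])].ravel()
        dist_sets[(a, b)] = vals
        rows.append({"segment_a": a, "segment_b": b,
                     "distance_class": segment_pair_class(a, b),
                     "n_pairs": len(vals), "mean": float(vals.mean()),
                     "median": float(np.median(vals))})
    pair_distances = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    comp_rows = []
    pairs = list(dist_sets)
    for (p1, p2) in itertools.combinations(pairs, 2):
        if not set(p1) & set(p2):
            continue  # only compare segment pairs sharing a segment
        x, y = dist_sets[p1], dist_sets[p2]
        degenerate = np.all(np.concatenate([x, y]) == x[0]) if len(x) else True
        p = 1.0 if degenerate else _mean_diff_permutation_p(x, y, n_perm, rng)
        comp_rows.append({"pair_1": "-".join(p1), "pair_2": "-".join(p2),
                          "p": p, "degenerate": degenerate})
    comparisons = pd.DataFrame(comp_rows)
    if len(comparisons):
        comparisons["p_holm"] = _holm(comparisons["p"].to_numpy())
    return pair_distances, comparisons


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def intra_inter_group_distances(dm: DistanceMatrix, groups: pd.Series,
                                mode: str = "auto"):
    """Within- and between-group pairwise distance sets with comparisons.

    Partitions all sample pairs by the groups of their endpoints.  For each
    unordered group pair, the two within-group sets are compared with a
    two-sided Wilcoxon rank-sum test (dispersion contrast).  Singleton
    groups have an empty within-set and NaN comparisons.

    Returns ``(within, between, tests)`` where ``within`` maps group ->
    distances, ``between`` maps (group_a, group_b) -> distances.
    """
    groups = groups.loc[list(dm.ids)]
    names = list(pd.unique(groups))
    if len(names) < 2:
        raise InputError("need at least 2 groups")
    d = np.asarray(dm.data)
    idx = {g: np.flatnonzero((groups == g).to_numpy()) for g in names}
    within = {}
    for g, ii in idx.items():
        pairs = [d[i, j] for i, j in itertools.combinations(ii, 2)]
        within[g] = np.asarray(pairs)
    between = {
        (a, b): d[np.ix_(idx[a], idx[b])].ravel()
        for a, b in itertools.combinations(names, 2)
    }
    rows = []
    for a, b in itertools.combinations(names, 2):
        wa, wb = within[a], within[b]
        p = (wilcoxon_rank_sum(wa, wb, mode=mode)
             if len(wa) and len(wb) else np.nan)
        rows.append({"group_a": a, "group_b": b, "p_within_vs_within": p,
                     "n_a": len(wa), "n_b": len(wb)})
    return within, between, pd.DataFrame(rows)
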