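"""Stratified differential testing with Cliff's delta and permutation p-values.

Features (taxa or metabolites) are screened per sex x site stratum: the
effect size is Cliff's delta between the medium-fat and low-fat diet groups
(positive = enriched under MFD), significance comes from a two-sided label
permutation test, and Benjamini-Hochberg q-values are computed within each
stratum by default.  Cross-segment genus summaries report the per-segment
delta with bootstrap variability (pigs resampled within diet groups), the
statistic behind forest-plot displays.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import DIETS, SEXES
from .preprocess import InputError
from .stats import (
    _EPS,
    bh_fdr,
    cliffs_delta,
    permutation_test_delta,
    wilcoxon_rank_sum,
)

__all__ = [
    "cliffs_delta",
    "permutation_test_delta",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "differential_screen",
    "screen_stratum",
    "aggregate_lineage",
    "screen_all_ranks",
    "class_aggregate",
    "presence_shift",
    "bootstrap_segment_aggregate",
    "EffectAggregate",
    "top_responsive",
    "log2_fold_change",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


# --------------------------------------------------------------------------
# vectorised stratum screen
# --------------------------------------------------------------------------


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, axis=1, method="average")


def screen_stratum(matrix: pd.DataFrame, is_mfd: np.ndarray,
                   n_perm: int = 2000, seed=0) -> pd.DataFrame:
    """Delta + permutation p for every feature of one stratum, vectorised.

    ``matrix`` is features x samples restricted to the stratum; ``is_mfd``
    marks the MFD columns.  All features share the same label permutations
    (exhaustive when C(n, n_mfd) <= n_perm, Monte Carlo otherwise), and the
    per-feature statistics are computed from mid-rank sums, which equal the
    pairwise-count definition of Cliff's delta.
    """
    is_mfd = np.asarray(is_mfd, dtype=bool)
    n = len(is_mfd)
    m = int(is_mfd.sum())
    k = n - m
    if m == 0 or k == 0:
        raise InputError("stratum must contain both diet groups")
    x = matrix.to_numpy(dtype=float)
    ranks = _rank_rows(x)
    mfd_idx = np.flatnonzero(is_mfd)

    def deltas_for(idx: np.ndarray) -> np.ndarray:
        # idx: (B, m) column subsets; returns (F, B) deltas
        u = ranks[:, idx].sum(axis=2) - m * (m + 1) / 2.0
        return 2.0 * u / (m * k) - 1.0

    obs = deltas_for(mfd_idx[None, :])[:, 0]
    n_comb = math.comb(n, m)
    if n_comb <= n_perm:
        idx = np.fromiter(
            itertools.chain.from_iterable(itertools.combinations(range(n), m)),
            dtype=np.intp, count=n_comb * m,
        ).reshape(n_comb, m)
        null = deltas_for(idx)
        p = np.count_nonzero(np.abs(null) >= np.abs(obs)[:, None] - _EPS, axis=1) / n_comb
        n_used, method = n_comb, "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
        null = deltas_for(idx)
        exceed = np.count_nonzero(np.abs(null) >= np.abs(obs)[:, None] - _EPS, axis=1)
        p = (1.0 + exceed) / (n_perm + 1.0)
        n_used, method = n_perm, "monte-carlo"
    # constant features carry no information: delta 0, p 1
    constant = (x == x[:, :1]).all(axis=1)
    obs[constant] = 0.0
    p[constant] = 1.0
    return pd.DataFrame({
        "feature_id": matrix.index, "delta": obs, "p_perm": p,
        "n_perm": n_used, "method": method, "n_mfd": m, "n_lfd": k,
    })


def differential_screen(matrix: pd.DataFrame, metadata: pd.DataFrame,
                        n_perm: int = 2000, seed=0,
                        fdr_scope: str = "stratum") -> pd.DataFrame:
    """Screen every feature in every sex x site stratum.

    ``metadata`` (indexed by sample id) must provide ``sex``, ``diet`` and
    ``site`` for the columns of ``matrix``.  Strata missing one of the two
    diets are skipped with a warning.  q-values are Benjamini-Hochberg,
    computed within each stratum (``fdr_scope='stratum'``, matching
    per-panel presentation) or across all records (``'global'``).
    """
    meta = metadata.loc[matrix.columns]
    records = []
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    strata = list(itertools.product(pd.unique(meta["sex"]), pd.unique(meta["site"])))
    children = ss.spawn(len(strata))
    for (sex, site), child in zip(strata, children):
        sel = (meta["sex"] == sex) & (meta["site"] == site)
        if not sel.any():
            continue
        sub = matrix.loc[:, sel.to_numpy()]
        diets = meta.loc[sel, "diet"]
        if len(pd.unique(diets)) < 2:
            warnings.warn(f"stratum ({sex}, {site}) lacks a diet group; skipped",
                          stacklevel=2)
            continue
        rec = screen_stratum(sub, (diets == "MFD").to_numpy(), n_perm=n_perm, seed=child)
        rec.insert(1, "sex", sex)
        rec.insert(2, "site", site)
        if fdr_scope == "stratum":
            rec["q"] = bh_fdr(rec["p_perm"].to_numpy())
        records.append(rec)
    if not records:
        return pd.DataFrame(columns=["feature_id", "sex", "site", "delta",
                                     "p_perm", "q", "n_perm", "method",
                                     "n_mfd", "n_lfd"])
    out = pd.concat(records, ignore_index=True)
    if fdr_scope == "global":
        out["q"] = bh_fdr(out["p_perm"].to_numpy())
    elif fdr_scope != "stratum":
        raise InputError(f"unknown fdr_scope {fdr_scope!r}")
    out["direction"] = np.where(out["delta"] > 0, "MFD",
                                np.where(out["delta"] < 0, "LFD", "none"))
    return out


# --------------------------------------------------------------------------
# lineage handling
# --------------------------------------------------------------------------


def parse_lineage(lineage: str):
    """Split a pipe-delimited lineage and validate its rank prefixes."""
    parts = lineage.split("|")
    if len(parts) > len(RANKS):
        raise InputError(f"lineage has more than {len(RANKS)} ranks: {lineage!r}")
    for part, prefix in zip(parts, _RANK_PREFIXES):
        if not part.startswith(prefix):
            raise InputError(f"malformed lineage (expected {prefix!r}): {lineage!r}")
    return parts


def aggregate_lineage(matrix: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Sum abundances up to a taxonomic rank; column sums are preserved.

    Rows must be pipe-delimited lineage strings reaching at least ``rank``;
    re-aggregating an already aggregated matrix is a no-op.
    """
    if rank not in RANKS:
        raise InputError(f"unknown rank {rank!r}")
    depth = RANKS.index(rank) + 1
    keys = []
    for lineage in matrix.index:
        parts = parse_lineage(str(lineage))
        if len(parts) < depth:
            raise InputError(
                f"row {lineage!r} does not reach rank {rank!r}")
        keys.append("|".join(parts[:depth]))
    out = matrix.groupby(pd.Index(keys, name=matrix.index.name)).sum()
    return out


def screen_all_ranks(matrix: pd.DataFrame, metadata: pd.DataFrame,
                     ranks=RANKS, n_perm: int = 2000, seed=0,
                     fdr_scope: str = "stratum") -> pd.DataFrame:
    """Differential screen of a species-level matrix at every requested rank."""
    frames = []
    ss = np.random.SeedSequence(seed).spawn(len(ranks))
    for rank, child in zip(ranks, ss):
        agg = aggregate_lineage(matrix, rank)
        rec = differential_screen(agg, metadata, n_perm=n_perm, seed=child,
                                  fdr_scope=fdr_scope)
        rec.insert(0, "rank", rank)
        frames.append(rec)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# metabolite class aggregation
# --------------------------------------------------------------------------


def log2_fold_change(mfd: np.ndarray, lfd: np.ndarray) -> float:
    """log2 of the MFD/LFD group-mean ratio with a scale-adaptive pseudocount.

    The pseudocount — half the smallest nonzero value across both groups —
    is only added when a zero is present, so zero-containing features get a
    finite fold change on their own scale while fully observed features are
    untouched; an all-zero feature returns 0.
    """
    pooled = np.concatenate([mfd, lfd])
    nonzero = pooled[pooled > 0]
    if nonzero.size == 0:
        return 0.0
    pc = nonzero.min() / 2.0 if np.any(pooled == 0) else 0.0
    return float(np.log2((mfd.mean() + pc) / (lfd.mean() + pc)))


def class_aggregate(matrix: pd.DataFrame, class_map: pd.Series,
                    metadata: pd.DataFrame, points: str = "means"):
    """Metabolite-class summaries: class sums, diet tests, member log2FCs.

    For every chemical class, member concentrations are summed per sample;
    a two-sided Wilcoxon rank-sum test compares the diet groups within each
    sex on those sums.  Each member metabolite also contributes a log2 fold
    change — of the group means by default (``points='means'``) or of every
    MFD sample against the LFD mean (``points='samples'``).  Metabolites
    absent from the class map are excluded with a warning.

    Returns ``(class_sums, tests, member_fc)``.
    """
    class_map = class_map.astype(str)
    unmapped = [m for m in matrix.index if m not in class_map.index]
    if unmapped:
        warnings.warn(f"{len(unmapped)} metabolite(s) missing from the class map; "
                      f"excluded: {unmapped[:5]}", stacklevel=2)
    mapped = matrix.loc[[m for m in matrix.index if m in class_map.index]]
    labels = class_map.loc[mapped.index]
    class_sums = mapped.groupby(labels.to_numpy()).sum()
    class_sums.index.name = "class"

    meta = metadata.loc[matrix.columns]
    tests = []
    fc_rows = []
    for sex in pd.unique(meta["sex"]):
        sel = (meta["sex"] == sex).to_numpy()
        diets = meta.loc[sel, "diet"]
        mfd_cols = diets.index[diets == "MFD"]
        lfd_cols = diets.index[diets == "LFD"]
        for cls in class_sums.index:
            p = (wilcoxon_rank_sum(class_sums.loc[cls, mfd_cols].to_numpy(),
                                   class_sums.loc[cls, lfd_cols].to_numpy())
                 if len(mfd_cols) and len(lfd_cols) else np.nan)
            tests.append({"class": cls, "sex": sex, "p_wilcoxon": p,
                          "n_mfd": len(mfd_cols), "n_lfd": len(lfd_cols)})
        for met in mapped.index:
            mfd_v = mapped.loc[met, mfd_cols].to_numpy(dtype=float)
            lfd_v = mapped.loc[met, lfd_cols].to_numpy(dtype=float)
            if points == "means":
                fc_rows.append({"metabolite_id": met, "class": labels[met],
                                "sex": sex,
                                "log2fc": log2_fold_change(mfd_v, lfd_v)})
            elif points == "samples":
                pooled = np.concatenate([mfd_v, lfd_v])
                nonzero = pooled[pooled > 0]
                pc = (nonzero.min() / 2.0
                      if nonzero.size and np.any(pooled == 0) else 0.0)
                ref = lfd_v.mean() + pc
                for sid, v in zip(mfd_cols, mfd_v):
                    fc_rows.append({"metabolite_id": met, "class": labels[met],
                                    "sex": sex, "sample_id": sid,
                                    "log2fc": float(np.log2((v + pc) / ref))})
            else:
                raise InputError(f"unknown points mode {points!r}")
    return class_sums, pd.DataFrame(tests), pd.DataFrame(fc_rows)


# --------------------------------------------------------------------------
# presence/absence shifts
# --------------------------------------------------------------------------


def presence_shift(matrix: pd.DataFrame, metadata: pd.DataFrame,
                   min_samples: int = 2, min_abundance: float = 0.0,
                   site: str = "") -> pd.DataFrame:
    """Features detected exclusively in one diet group.

    Within each sex, a feature "appeared in MFD" if it exceeds
    ``min_abundance`` in at least ``min_samples`` MFD samples and in zero
    LFD samples; "disappeared in MFD" is the symmetric call.
    """
    if min_samples < 1:
        raise InputError("min_samples must be at least 1")
    if min_abundance < 0:
        raise InputError("min_abundance must be nonnegative")
    meta = metadata.loc[matrix.columns]
    detected = matrix.to_numpy(dtype=float) > min_abundance
    rows = []
    for sex in pd.unique(meta["sex"]):
        mfd = ((meta["sex"] == sex) & (meta["diet"] == "MFD")).to_numpy()
        lfd = ((meta["sex"] == sex) & (meta["diet"] == "LFD")).to_numpy()
        n_mfd = detected[:, mfd].sum(axis=1)
        n_lfd = detected[:, lfd].sum(axis=1)
        for i, fid in enumerate(matrix.index):
            direction = None
            if n_mfd[i] >= min_samples and n_lfd[i] == 0:
                direction = "appeared_in_MFD"
            elif n_lfd[i] >= min_samples and n_mfd[i] == 0:
                direction = "disappeared_in_MFD"
            if direction:
                rows.append({"feature_id": fid, "site": site, "sex": sex,
                             "direction": direction,
                             "n_detected_mfd": int(n_mfd[i]),
                             "n_detected_lfd": int(n_lfd[i])})
    return pd.DataFrame(rows, columns=["feature_id", "site", "sex", "direction",
                                       "n_detected_mfd", "n_detected_lfd"])


# --------------------------------------------------------------------------
# bootstrap cross-segment aggregation (forest-plot statistics)
# --------------------------------------------------------------------------


@dataclass
class SegmentEffect:
    delta: float
    boot_sd: float
    ci_low: float
    ci_high: float
    present: bool
    degenerate: bool = False


@dataclass
class EffectAggregate:
    """Per-segment delta of one genus with bootstrap variability."""

    genus_id: str
    sex: str
    segments: dict = field(default_factory=dict)


def _bootstrap_deltas(x: np.ndarray, y: np.ndarray, n_boot: int, rng) -> np.ndarray:
    ia = rng.integers(0, len(x), size=(n_boot, len(x)))
    ib = rng.integers(0, len(y), size=(n_boot, len(y)))
    xa = x[ia]
    yb = y[ib]
    return np.sign(xa[:, :, None] - yb[:, None, :]).mean(axis=(1, 2))


def bootstrap_segment_aggregate(matrices: dict, genus_id: str,
                                metadata: pd.DataFrame, sex: str,
                                n_boot: int = 1000, seed=0,
                                ci_level: float = 0.95) -> EffectAggregate:
    """Cross-segment effect summary for one genus-level feature.

    For every segment where the genus row exists and is detected, pigs are
    resampled with replacement within each diet group and Cliff's delta
    recomputed ``n_boot`` times; the bootstrap SD and the percentile
    interval at ``ci_level`` accompany the plug-in delta.  Segments where
    the genus is undetected are flagged absent, never imputed; diet groups
    of size 1 yield a degenerate-flagged bootstrap.
    """
    if not matrices:
        raise InputError("need at least one segment matrix")
    rng = np.random.default_rng(seed)
    lo_q, hi_q = 100 * (1 - ci_level) / 2, 100 * (1 + ci_level) / 2
    agg = EffectAggregate(genus_id, sex)
    found = False
    for seg, matrix in matrices.items():
        if genus_id not in matrix.index:
            agg.segments[seg] = SegmentEffect(np.nan, np.nan, np.nan, np.nan, False)
            continue
        meta = metadata.loc[matrix.columns]
        sel = (meta["sex"] == sex).to_numpy()
        vals = matrix.loc[genus_id].to_numpy(dtype=float)[sel]
        diets = meta.loc[sel, "diet"].to_numpy()
        x = vals[diets == "MFD"]
        y = vals[diets == "LFD"]
        if np.all(vals == 0) or len(x) == 0 or len(y) == 0:
            agg.segments[seg] = SegmentEffect(np.nan, np.nan, np.nan, np.nan, False)
            continue
        found = True
        delta = cliffs_delta(x, y)
        if len(x) < 2 or len(y) < 2:
            agg.segments[seg] = SegmentEffect(delta, np.nan, np.nan, np.nan,
                                              True, degenerate=True)
            continue
        boots = _bootstrap_deltas(x, y, n_boot, rng)
        agg.segments[seg] = SegmentEffect(
            delta, float(boots.std(ddof=1)),
            float(np.percentile(boots, lo_q)), float(np.percentile(boots, hi_q)),
            True)
    if not found:
        raise InputError(f"genus {genus_id!r} detected in no segment")
    return agg


def top_responsive(records: pd.DataFrame, n: int = 500) -> pd.DataFrame:
    """The n features with the largest max |delta| across sites.

    The ranking key is the maximum absolute Cliff's delta over all strata a
    feature was tested in.
    """
    key = records.assign(abs_delta=records["delta"].abs())
    ranked = (key.groupby("feature_id")["abs_delta"].max()
              .sort_values(ascending=False).head(n))
    return records[records["feature_id"].isin(ranked.index)].copy()
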