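"""Cross-omics Spearman correlation blocks, density matrices and triads.

Layers (per-segment microbiota, per-compartment metabolomes, host
phenotypes) are matched by pig and correlated pairwise with Spearman's
rank correlation.  The summary statistic across a block is the proportion
of pairs significant at raw p <= alpha — the "density" of associations —
computed separately per diet x sex condition so conditions can be
contrasted.  Metabolites can first be restricted to those annotated as
linked to bacterial metabolism via a user-supplied flag table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .preprocess import InputError
from .stats import _EPS, spearman

__all__ = [
    "spearman",
    "CorrelationBlock",
    "correlation_block",
    "density_matrix",
    "annotation_filter",
    "load_annotation_map",
    "triad_screen",
    "pig_matrix",
]

MIN_SHARED_PIGS = 4


@dataclass
class CorrelationBlock:
    """All pairwise Spearman results between two pig-matched layers."""

    layer_a: str
    layer_b: str
    rho: pd.DataFrame  # A features x B features
    p: pd.DataFrame
    n: int
    condition: str = ""

    def tidy(self) -> pd.DataFrame:
        rows = []
        for a in self.rho.index:
            for b in self.rho.columns:
                rows.append({"layer_a": self.layer_a, "id_a": a,
                             "layer_b": self.layer_b, "id_b": b,
                             "rho": self.rho.loc[a, b], "p": self.p.loc[a, b],
                             "n": self.n, "condition": self.condition})
        return pd.DataFrame(rows)


def pig_matrix(matrix: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Re-key the sample columns of a matrix by pig id."""
    pigs = metadata.loc[matrix.columns, "pig_id"]
    out = matrix.copy()
    out.columns = pigs.to_numpy()
    return out


def _rank_standardise(x: np.ndarray) -> np.ndarray:
    """Mid-ranks standardised per row; constant rows become all-zero."""
    r = sps.rankdata(x, axis=1, method="average")
    r = r - r.mean(axis=1, keepdims=True)
    sd = r.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant features -> zero scores -> rho 0, flagged later
    return r / sd


def correlation_block(a: pd.DataFrame, b: pd.DataFrame,
                      layer_a: str = "A", layer_b: str = "B",
                      condition: str = "", n_perm: int = 2000,
                      seed=0) -> CorrelationBlock | None:
    """Spearman correlations between every feature pair of two layers.

    ``a`` and ``b`` are features x pigs matrices (see :func:`pig_matrix`);
    only shared pigs are used, and a block with fewer than 4 shared pigs is
    skipped with a warning (returns None).  For n >= 10 pigs, p-values use
    the t approximation; for smaller n the whole block shares ``n_perm``
    joint column permutations, giving every pair a Monte-Carlo permutation
    p with the add-one estimator.  Constant features yield NaN rho/p.
    """
    shared = [p for p in a.columns if p in set(b.columns)]
    if len(shared) < MIN_SHARED_PIGS:
        warnings.warn(f"block {layer_a} x {layer_b}: only {len(shared)} shared "
                      "pigs; skipped", stacklevel=2)
        return None
    n = len(shared)
    xa = a[shared].to_numpy(dtype=float)
    xb = b[shared].to_numpy(dtype=float)
    za = _rank_standardise(xa)
    zb = _rank_standardise(xb)
    rho = za @ zb.T / n

    if n >= 10:
        denom = np.maximum(1.0 - rho**2, _EPS)
        t = rho * np.sqrt((n - 2) / denom)
        p = 2.0 * sps.t.sf(np.abs(t), n - 2)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(rho, dtype=np.int64)
        abs_obs = np.abs(rho) - _EPS
        for _ in range(n_perm):
            perm = rng.permutation(n)
            null = za @ zb[:, perm].T / n
            exceed += np.abs(null) >= abs_obs
        p = (1.0 + exceed) / (n_perm + 1.0)

    const_a = (xa == xa[:, :1]).all(axis=1)
    const_b = (xb == xb[:, :1]).all(axis=1)
    rho[const_a, :] = np.nan
    rho[:, const_b] = np.nan
    p[const_a, :] = np.nan
    p[:, const_b] = np.nan
    return CorrelationBlock(
        layer_a, layer_b,
        pd.DataFrame(rho, index=a.index, columns=b.index),
        pd.DataFrame(p, index=a.index, columns=b.index),
        n, condition,
    )


def density_matrix(blocks, alpha: float = 0.05) -> pd.DataFrame:
    """Proportion of significant pairs per layer pair.

    ``blocks`` is an iterable of :class:`CorrelationBlock` (typically all
    site x layer combinations of one diet x sex condition).  Each entry is
    ``#{p <= alpha} / total pairs`` over the block's finite p-values;
    missing blocks simply leave NaN entries, they are never counted as 0.
    The returned square DataFrame is symmetric across its layer labels.
    """
    if not 0 <= alpha <= 1:
        raise InputError("alpha must lie in [0, 1]")
    layers = []
    for blk in blocks:
        for name in (blk.layer_a, blk.layer_b):
            if name not in layers:
                layers.append(name)
    out = pd.DataFrame(np.nan, index=layers, columns=layers)
    for blk in blocks:
        p = blk.p.to_numpy(dtype=float)
        finite = np.isfinite(p)
        total = int(finite.sum())
        if total == 0:
            continue
        dens = float(np.count_nonzero(p[finite] <= alpha)) / total
        out.loc[blk.layer_a, blk.layer_b] = dens
        out.loc[blk.layer_b, blk.layer_a] = dens
    return out


# --------------------------------------------------------------------------
# annotation filtering
# --------------------------------------------------------------------------


def load_annotation_map(path) -> pd.Series:
    """Read a 2-column TSV (metabolite_id, flag) into a boolean series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise InputError("annotation map needs columns metabolite_id and flag")
    ids = df.iloc[:, 0].astype(str)
    flags = df.iloc[:, 1]
    if flags.dtype == object:
        flags = flags.astype(str).str.strip().str.lower().isin(("1", "true", "yes"))
    return pd.Series(flags.astype(bool).to_numpy(), index=ids)


def annotation_filter(metabolite_ids, annotation: pd.Series) -> list:
    """Metabolites flagged as linked to bacterial metabolism, order preserved.

    Metabolites absent from the map default to excluded.
    """
    flagged = set(annotation.index[annotation.astype(bool)])
    return [m for m in metabolite_ids if m in flagged]


# --------------------------------------------------------------------------
# microbe-metabolite-phenotype triads
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Triad:
    taxon_id: str
    taxon_site: str
    metabolite_id: str
    compartment: str
    phenotype: str
    rho_taxon_metabolite: float
    rho_taxon_phenotype: float
    rho_metabolite_phenotype: float
    p_taxon_metabolite: float
    p_taxon_phenotype: float
    p_metabolite_phenotype: float

    @property
    def min_abs_rho(self) -> float:
        return min(abs(self.rho_taxon_metabolite), abs(self.rho_taxon_phenotype),
                   abs(self.rho_metabolite_phenotype))


def triad_screen(taxa: pd.DataFrame, metabolites: pd.DataFrame,
                 phenotypes: pd.DataFrame, alpha: float = 0.05,
                 taxon_site: str = "", compartment: str = "",
                 n_perm: int = 2000, seed=0) -> list:
    """Taxon-metabolite-phenotype triples significant on all three edges.

    All three layers are features x pigs (phenotypes transposed to
    phenotype x pig).  A triad is reported when each pairwise Spearman
    p-value is <= ``alpha`` on the shared pigs; results are ranked by the
    weakest of the three correlations, strongest first.
    """
    shared = [p for p in taxa.columns
              if p in set(metabolites.columns) and p in set(phenotypes.columns)]
    if len(shared) < MIN_SHARED_PIGS:
        raise InputError(f"need at least {MIN_SHARED_PIGS} shared pigs, got {len(shared)}")
    ss = np.random.SeedSequence(seed).spawn(3)
    tm = correlation_block(taxa[shared], metabolites[shared], "taxa", "metabolites",
                           n_perm=n_perm, seed=ss[0])
    tp = correlation_block(taxa[shared], phenotypes[shared], "taxa", "phenotypes",
                           n_perm=n_perm, seed=ss[1])
    mp = correlation_block(metabolites[shared], phenotypes[shared], "metabolites",
                           "phenotypes", n_perm=n_perm, seed=ss[2])
    triads = []
    if alpha <= 0:
        return triads
    tm_sig = tm.p.le(alpha)
    tp_sig = tp.p.le(alpha)
    mp_sig = mp.p.le(alpha)
    for t in taxa.index:
        mets = tm_sig.columns[tm_sig.loc[t]]
        phes = tp_sig.columns[tp_sig.loc[t]]
        if len(mets) == 0 or len(phes) == 0:
            continue
        for m_, ph in itertools.product(mets, phes):
            if not mp_sig.loc[m_, ph]:
                continue
            triads.append(Triad(
                t, taxon_site, m_, compartment, ph,
                float(tm.rho.loc[t, m_]), float(tp.rho.loc[t, ph]),
                float(mp.rho.loc[m_, ph]),
                float(tm.p.loc[t, m_]), float(tp.p.loc[t, ph]),
                float(mp.p.loc[m_, ph]),
            ))
    triads.sort(key=lambda tr: -tr.min_abs_rho)
    return triads


def triad_table(triads) -> pd.DataFrame:
    return pd.DataFrame([{
        "taxon_id": t.taxon_id, "taxon_site": t.taxon_site,
        "metabolite_id": t.metabolite_id, "compartment": t.compartment,
        "phenotype": t.phenotype,
        "rho_taxon_metabolite": t.rho_taxon_metabolite,
        "rho_taxon_phenotype": t.rho_taxon_phenotype,
        "rho_metabolite_phenotype": t.rho_metabolite_phenotype,
        "p_taxon_metabolite": t.p_taxon_metabolite,
        "p_taxon_phenotype": t.p_taxon_phenotype,
        "p_metabolite_phenotype": t.p_metabolite_phenotype,
        "min_abs_rho": t.min_abs_rho,
    } for t in triads])
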