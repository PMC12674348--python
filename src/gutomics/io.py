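"""Readers and writers for the pipeline's table dialects.

Taxonomic profiles use the merged-profiler dialect: a TSV whose first
column holds pipe-delimited 7-rank lineages and whose remaining columns
hold per-sample relative abundances in percent; comment lines start with
``#``.  Metabolite tables are wide CSVs (metabolite x sample) in which
cells may carry a ``<LOD`` marker for values below the limit of detection.
All writers prepend a provenance header (version, seed, config hash) as
``#`` comment lines that every reader tolerates.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import RANKS, aggregate_lineage, parse_lineage
from .preprocess import InputError, RarefactionCurve

__version__ = "0.1.0"


class ParseError(ValueError):
    """Raised on malformed input tables."""


def provenance_header(seed=None, config_hash: str = "") -> str:
    parts = [f"# gutomics v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if config_hash:
        parts.append(f"# config: {config_hash}")
    return "\n".join(parts) + "\n"


def config_digest(mapping: dict) -> str:
    """Short stable digest of a configuration mapping."""
    canon = repr(sorted((str(k), str(v)) for k, v in mapping.items()))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, config_hash: str = "",
                sep: str = "\t", index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, config_hash))
        df.to_csv(fh, sep=sep, index=index)


# --------------------------------------------------------------------------
# taxonomic profiles
# --------------------------------------------------------------------------


def write_profiles(profiles: pd.DataFrame, path, seed=None,
                   config_hash: str = "") -> None:
    """Write a taxa x samples percent-abundance matrix as a lineage TSV."""
    out = profiles.copy()
    out.index.name = "lineage"
    write_table(out, path, seed=seed, config_hash=config_hash)


def read_profiles(path) -> pd.DataFrame:
    """Read a merged-profile TSV into a species-level abundance matrix.

    Rows at ranks above species are tolerated: they are dropped in favour
    of the species rows, after checking that re-aggregating the species
    rows reproduces them (a mismatch above 1e-6 triggers a warning).
    Inconsistent lineages raise a parse error naming the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty profile file") from None
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found")
    depths = {}
    for line_no, lineage in enumerate(df.index, start=1):
        try:
            parts = parse_lineage(str(lineage))
        except InputError as exc:
            raise ParseError(f"{path}: row {line_no}: {exc}") from None
        depths[lineage] = len(parts)
    species = df.loc[[l for l in df.index if depths[l] == len(RANKS)]]
    if species.empty:
        raise ParseError(f"{path}: no species-level rows")
    higher = df.loc[[l for l in df.index if depths[l] < len(RANKS)]]
    if not higher.empty:
        for lineage in higher.index:
            rank = RANKS[depths[lineage] - 1]
            recomputed = aggregate_lineage(species, rank)
            if lineage not in recomputed.index:
                raise ParseError(
                    f"{path}: aggregate row {lineage!r} has no species descendants")
            diff = np.abs(recomputed.loc[lineage] - higher.loc[lineage]).max()
            if diff > 1e-6:
                warnings.warn(
                    f"{path}: aggregate row {lineage!r} disagrees with the sum of "
                    f"its species by up to {diff:.3g}; species rows kept",
                    stacklevel=2)
    if np.any(species.to_numpy(dtype=float) < 0):
        raise ParseError(f"{path}: negative abundances")
    return species


# --------------------------------------------------------------------------
# metabolite tables
# --------------------------------------------------------------------------


def write_metabolites(matrix: pd.DataFrame, path, seed=None,
                      config_hash: str = "") -> None:
    out = matrix.copy()
    out.index.name = "metabolite_id"
    write_table(out, path, seed=seed, config_hash=config_hash, sep=",")


def read_class_map(path) -> pd.Series:
    """Read a metabolite -> class table (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: class map needs id and class columns")
    return pd.Series(df.iloc[:, 1].astype(str).to_numpy(),
                     index=df.iloc[:, 0].astype(str))


def read_metabolites(path, class_map_path=None, lod=None):
    """Read a metabolite x sample concentration CSV.

    ``<LOD`` cells are imputed to half the limit of detection (``lod`` may
    be a scalar or a metabolite -> LOD mapping) and flagged; without a
    known LOD they become 0 with a warning.  Metabolites absent from the
    class map are labelled ``Unclassified`` with a warning.

    Returns ``(matrix, classes, lod_flags)``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, comment="#", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty metabolite file") from None
    if raw.index.duplicated().any():
        dupes = list(raw.index[raw.index.duplicated()])
        raise ParseError(f"{path}: duplicate metabolite ids: {dupes[:5]}")
    is_lod = raw.apply(lambda col: col.astype(str).str.strip().str.upper() == "<LOD")
    values = raw.mask(is_lod).apply(pd.to_numeric)
    if is_lod.to_numpy().any():
        if lod is None:
            warnings.warn(f"{path}: <LOD cells without a known LOD set to 0",
                          stacklevel=2)
            fill = pd.Series(0.0, index=raw.index)
        elif np.isscalar(lod):
            fill = pd.Series(float(lod) / 2.0, index=raw.index)
        else:
            fill = pd.Series({m: float(lod[m]) / 2.0 for m in raw.index})
        for m in raw.index:
            values.loc[m] = values.loc[m].fillna(fill[m])
    matrix = values.astype(float)
    if class_map_path is not None:
        cmap = read_class_map(class_map_path)
        missing = [m for m in matrix.index if m not in cmap.index]
        if missing:
            warnings.warn(f"{path}: {len(missing)} metabolite(s) missing from the "
                          f"class map; labelled Unclassified: {missing[:5]}",
                          stacklevel=2)
        classes = pd.Series(
            [cmap.get(m, "Unclassified") for m in matrix.index], index=matrix.index)
    else:
        classes = pd.Series("Unclassified", index=matrix.index)
    return matrix, classes, is_lod


# --------------------------------------------------------------------------
# rarefaction curves / qPCR
# --------------------------------------------------------------------------


def write_rarefaction(curves, path, seed=None, config_hash: str = "") -> None:
    """Write curves as a long TSV (sample_id, depth, markers)."""
    rows = [
        {"sample_id": c.sample_id, "depth": int(d), "markers": int(m)}
        for c in curves for d, m in zip(c.depths, c.markers)
    ]
    write_table(pd.DataFrame(rows), path, seed=seed, config_hash=config_hash,
                index=False)


def read_rarefaction(path) -> list:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"sample_id", "depth", "markers"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}")
    curves = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("depth")
        curves.append(RarefactionCurve(str(sid), grp["depth"].to_numpy(),
                                       grp["markers"].to_numpy()))
    return curves


def write_qpcr(ct_table: pd.DataFrame, standards: pd.DataFrame, ct_path,
               standards_path, seed=None, config_hash: str = "") -> None:
    write_table(ct_table, ct_path, seed=seed, config_hash=config_hash, index=False)
    write_table(standards, standards_path, seed=seed, config_hash=config_hash,
                index=False)


def read_qpcr(ct_path, standards_path):
    ct = pd.read_csv(ct_path, sep="\t", comment="#")
    std = pd.read_csv(standards_path, sep="\t", comment="#")
    for df, cols, path in ((ct, {"sample_id", "ct", "dilution_factor", "mass_mg"}, ct_path),
                           (std, {"log10_copies", "ct"}, standards_path)):
        if not cols.issubset(df.columns):
            raise ParseError(f"{path}: expected columns {sorted(cols)}")
    return ct, std


def write_metadata(samples: pd.DataFrame, path, seed=None,
                   config_hash: str = "") -> None:
    write_table(samples, path, seed=seed, config_hash=config_hash, sep=",",
                index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    needed = {"sample_id", "pig_id", "sex", "diet", "site"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(needed)}")
    return df
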