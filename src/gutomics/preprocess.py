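"""Depth QC, count subsampling, absolute qPCR loads and host indices.

Sequencing-depth adequacy is judged from rarefaction curves: the marginal
marker-gene discovery rate at the deepest sampled depth (the "end slope").
Samples whose end slope exceeds 0.075 marker genes per read pair are deemed
undersequenced and excluded; rarefied analyses then subsample every kept
sample of a segment to that segment's minimum depth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_QC_THRESHOLD = 0.075  # marker genes per read pair


class InputError(ValueError):
    """Raised on malformed analysis inputs."""


class DepthError(ValueError):
    """Raised when a requested subsampling depth is unattainable."""


class AnalysisError(RuntimeError):
    """Raised when a contract of a downstream analysis cannot be met."""


@dataclass(frozen=True)
class RarefactionCurve:
    """Marker-gene discovery as a function of sequencing depth.

    ``depths`` must be strictly increasing read-pair counts and ``markers``
    the non-decreasing marker-gene tallies observed at those depths.
    """

    sample_id: str
    depths: np.ndarray
    markers: np.ndarray

    def __post_init__(self):
        depths = np.asarray(self.depths, dtype=float)
        markers = np.asarray(self.markers, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "markers", markers)
        if depths.shape != markers.shape or depths.ndim != 1:
            raise InputError(f"{self.sample_id}: depths and markers must be equal-length vectors")
        if len(depths) < 2:
            raise InputError(f"{self.sample_id}: a curve needs at least 2 points")
        if not np.all(np.diff(depths) > 0):
            raise InputError(f"{self.sample_id}: depths must be strictly increasing")
        if not np.all(np.diff(markers) >= 0):
            raise InputError(f"{self.sample_id}: marker counts must be non-decreasing")

    @property
    def final_depth(self) -> float:
        return float(self.depths[-1])


@dataclass(frozen=True)
class QcDecision:
    sample_id: str
    end_slope: float
    kept: bool
    threshold: float


@dataclass(frozen=True)
class StandardCurve:
    """Ct as a linear function of log10 template copies per reaction."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self):
        if self.slope >= 0:
            raise InputError("standard curve slope must be negative (more template, lower Ct)")


@dataclass(frozen=True)
class LoadResult:
    sample_id: str
    copies_per_gram: float
    ct: float
    dilution_factor: float
    mass_mg: float


def end_slope(curve: RarefactionCurve, n_tail: int = 2) -> float:
    """Terminal discovery rate of a rarefaction curve.

    By default the slope of the secant through the final two points, in
    marker genes per read pair.  ``n_tail > 2`` instead fits a least-squares
    line through the last ``n_tail`` points, a smoother variant for noisy
    curves.
    """
    if n_tail < 2:
        raise InputError("n_tail must be at least 2")
    n_tail = min(n_tail, len(curve.depths))
    d = curve.depths[-n_tail:]
    m = curve.markers[-n_tail:]
    if n_tail == 2:
        return float((m[1] - m[0]) / (d[1] - d[0]))
    return float(np.polyfit(d, m, 1)[0])


def qc_filter(curves, threshold: float = DEFAULT_QC_THRESHOLD, n_tail: int = 2):
    """Flag undersequenced samples by the end-slope rule.

    A sample is kept iff its end slope is <= ``threshold``; the boundary is
    kept, since only slopes strictly above the threshold indicate
    insufficient depth.
    """
    if threshold <= 0:
        raise InputError("threshold must be positive")
    return [
        QcDecision(c.sample_id, s, s <= threshold, threshold)
        for c in curves
        for s in (end_slope(c, n_tail=n_tail),)
    ]


def qc_table(decisions) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": d.sample_id, "end_slope": d.end_slope,
          "kept": d.kept, "threshold": d.threshold} for d in decisions]
    )


def subsample_counts(counts, target_depth: int, seed) -> np.ndarray:
    """Rarefy a count vector to ``target_depth`` without replacement.

    A multivariate hypergeometric draw: the count-level abstraction of
    subsampling a fixed number of read pairs from a library.  The result
    sums exactly to ``target_depth`` and is deterministic for a given seed.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        rounded = np.rint(counts)
        if not np.allclose(counts, rounded):
            raise InputError("counts must be integral")
        counts = rounded.astype(np.int64)
    if np.any(counts < 0):
        raise InputError("counts must be nonnegative")
    total = int(counts.sum())
    target_depth = int(target_depth)
    if target_depth > total:
        raise DepthError(f"target depth {target_depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, target_depth)


def rarefy_matrix(counts: pd.DataFrame, target_depth: int, seed) -> pd.DataFrame:
    """Rarefy every column of a features x samples count matrix."""
    ss = np.random.SeedSequence(seed).spawn(counts.shape[1])
    out = {
        sid: subsample_counts(counts[sid].to_numpy(), target_depth, child)
        for sid, child in zip(counts.columns, ss)
    }
    return pd.DataFrame(out, index=counts.index)


def segment_depth_policy(depths: pd.Series, segments: pd.Series, kept) -> dict:
    """Common rarefaction depth per segment: the minimum among kept samples.

    ``depths``/``segments`` are indexed by sample id; ``kept`` is the subset
    of sample ids that passed QC.  Raises if any segment loses all samples.
    """
    kept = list(kept)
    empty = []
    targets = {}
    for seg in pd.unique(segments):
        ids = [s for s in segments.index[segments == seg] if s in kept]
        if not ids:
            empty.append(seg)
        else:
            targets[seg] = int(min(depths[s] for s in ids))
    if empty:
        raise AnalysisError(f"all samples excluded by QC in segment(s): {', '.join(map(str, empty))}")
    return targets


def fit_standard_curve(log10_copies, ct) -> StandardCurve:
    """Ordinary least squares of Ct on log10 copies per reaction."""
    x = np.asarray(log10_copies, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) < 3:
        raise InputError("a standard curve needs at least 3 dilution points")
    if len(np.unique(x)) < 2:
        raise InputError("dilution points must span distinct log10 values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return StandardCurve(float(slope), float(intercept), r2)


def qpcr_load(ct: float, curve: StandardCurve, dilution_factor: float,
              sample_mass_mg: float, sample_id: str = "") -> LoadResult:
    """Back-calculate absolute 16S copies per gram of sample.

    Inverts the standard curve to copies per reaction, then scales by the
    cumulative dilution factor of the DNA purification and by the weighed
    sample mass.  Ct values outside the fitted standard range extrapolate
    (with a warning) rather than fail.
    """
    if sample_mass_mg <= 0:
        raise InputError("sample mass must be positive")
    if dilution_factor <= 0:
        raise InputError("dilution factor must be positive")
    log10_copies = (ct - curve.intercept) / curve.slope
    if log10_copies < 0:
        warnings.warn(
            f"{sample_id or 'sample'}: Ct {ct:.2f} is above the single-copy "
            "intercept; extrapolating below the standard range",
            stacklevel=2,
        )
    copies_rxn = 10.0**log10_copies
    copies_per_gram = copies_rxn * dilution_factor / (sample_mass_mg / 1000.0)
    return LoadResult(sample_id, copies_per_gram, ct, dilution_factor, sample_mass_mg)


def qpcr_load_table(ct_table: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Apply :func:`qpcr_load` to a plate table (sample_id, ct, dilution_factor, mass_mg)."""
    rows = []
    for _, r in ct_table.iterrows():
        res = qpcr_load(r.ct, curve, r.dilution_factor, r.mass_mg, sample_id=r.sample_id)
        rows.append({"sample_id": res.sample_id, "copies_per_gram": res.copies_per_gram,
                     "ct": res.ct, "dilution_factor": res.dilution_factor,
                     "mass_mg": res.mass_mg})
    return pd.DataFrame(rows)


def homa_ir(insulin_uU_per_mL, glucose_mg_per_dL):
    """Homeostatic model assessment of insulin resistance.

    HOMA-IR = insulin (µU/mL) x fasting glucose (mg/dL) / 405.
    """
    insulin = np.asarray(insulin_uU_per_mL, dtype=float)
    glucose = np.asarray(glucose_mg_per_dL, dtype=float)
    if np.any(insulin < 0) or np.any(glucose < 0):
        raise InputError("insulin and glucose must be nonnegative")
    out = insulin * glucose / 405.0
    return float(out) if out.ndim == 0 else out
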