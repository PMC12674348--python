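"""Study-design configuration for the synthetic cohort generator and pipeline.

The defaults encode the design of a two-diet (low-fat vs medium-fat) Iberian
pig feeding trial: two diets crossed with two sexes, ~9 pigs per cell,
metagenomic sampling at five gut segments ordered proximal to distal, and
targeted metabolomics of two compartments (bile and duodenojejunal fluid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

SEGMENTS = ("duodenojejunum", "jejunum", "ileum", "proximal_colon", "feces")
COMPARTMENTS = ("bile", "dj_fluid")
SEXES = ("female", "male")
DIETS = ("LFD", "MFD")

#: segments belonging to the small intestine (proximal) vs the distal gut;
#: used for distance-class labelling and the compositional gradient.
SMALL_INTESTINE = ("duodenojejunum", "jejunum", "ileum")
DISTAL = ("proximal_colon", "feces")

#: site aliases tolerated in input tables -> controlled vocabulary
SITE_ALIASES = {
    "duo_jej": "duodenojejunum",
    "duodenojejunal": "duodenojejunum",
    "dj": "duodenojejunum",
    "prox_col": "proximal_colon",
    "proximal colon": "proximal_colon",
    "stool": "feces",
    "faeces": "feces",
    "djf": "dj_fluid",
    "duodenojejunal_fluid": "dj_fluid",
}


class ConfigurationError(ValueError):
    """Raised when a configuration field violates its contract."""


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth signal planted into one generated layer.

    Parameters
    ----------
    feature_id :
        Identifier of the affected feature: a species lineage string for the
        taxon layer, a metabolite id or ``class:<name>`` for the metabolite
        layer, a phenotype column name, or a segment name for the ``load``
        layer.
    layer :
        One of ``taxon``, ``metabolite``, ``phenotype``, ``load``.
    strata :
        Sequence of ``(sex, site)`` cells the effect applies to.  ``sex`` may
        be ``None`` for both sexes; ``site`` may be ``None`` where the layer
        has no site (phenotypes).
    effect_size :
        Target Cliff's delta in [-1, 1] (``mode="delta"``, positive = higher
        in MFD) or a multiplicative MFD/LFD shift (``mode="multiplier"``).
    """

    feature_id: str
    layer: str
    strata: tuple
    effect_size: float
    mode: str = "delta"

    def __post_init__(self):
        if self.layer not in ("taxon", "metabolite", "phenotype", "load"):
            raise ConfigurationError(f"unknown layer {self.layer!r}")
        if self.mode not in ("delta", "multiplier"):
            raise ConfigurationError(f"unknown effect mode {self.mode!r}")
        if self.mode == "delta" and not -1.0 <= self.effect_size <= 1.0:
            raise ConfigurationError(
                f"effect_size: target delta must lie in [-1, 1], got {self.effect_size}"
            )
        if self.mode == "multiplier" and self.effect_size <= 0:
            raise ConfigurationError("effect_size: multiplier must be positive")
        if len(self.strata) == 0:
            raise ConfigurationError("strata: must be non-empty")


@dataclass(frozen=True)
class CorrelatedPair:
    """A taxon-metabolite pair generated with a true rank correlation."""

    taxon_id: str
    taxon_site: str
    metabolite_id: str
    compartment: str
    rho: float

    def __post_init__(self):
        if not -1.0 < self.rho < 1.0:
            raise ConfigurationError(f"rho must lie in (-1, 1), got {self.rho}")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterisation of the synthetic cohort.

    Sizes default to the study design being emulated (9 pigs per diet x sex
    cell, 5 segments, 2 compartments); feature counts are kept small enough
    for sub-minute generation while preserving the layered structure.
    """

    n_per_group: int = 9
    segments: tuple = SEGMENTS
    compartments: tuple = COMPARTMENTS
    n_taxa: int = 150
    n_metabolites: int = 120
    effect_table: tuple = ()
    correlated_pairs: tuple = ()
    seed: int = 0

    # latent-scale noise for taxon log-abundances; the planted-delta link
    # delta = 2*Phi(mu / sqrt(2) / sigma) - 1 is inverted against this sigma
    latent_sigma: float = 1.0
    centroid_sigma: float = 2.0
    detection_limit: float = 1e-3  # percent relative abundance
    distal_shift: float = 6.0  # latent log deficit of distal taxa proximally

    metabolome_sigma: float = 0.6  # log-scale noise of concentrations

    # sequencing-depth model: saturated samples sequenced deep, a fraction
    # left shallow so the rarefaction end-slope QC rule has true positives
    depth_range: tuple = (1.6e6, 2.4e6)
    unsaturated_depth_range: tuple = (1.6e5, 2.0e5)
    unsaturated_fraction: float = 0.1
    marker_pool: float = 1e5  # asymptote of the marker discovery curve
    discovery_scale: float = 1e6  # e-folding depth of the discovery curve
    n_curve_points: int = 10

    # qPCR plate model
    qpcr_slope: float = -3.32
    qpcr_intercept: float = 38.0
    qpcr_ct_noise: float = 0.15
    load_log10_by_segment: tuple = (7.0, 7.8, 8.6, 10.2, 11.0)
    load_log10_sd: float = 0.3
    dilution_factor: float = 100.0

    def __post_init__(self):
        if self.n_per_group < 3:
            raise ConfigurationError(
                f"n_per_group: need at least 3 pigs per group, got {self.n_per_group}"
            )
        for name in ("n_taxa", "n_metabolites", "n_curve_points"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name}: must be positive")
        if len(self.segments) == 0 or len(self.compartments) == 0:
            raise ConfigurationError("segments/compartments: must be non-empty")
        if len(self.load_log10_by_segment) != len(self.segments):
            raise ConfigurationError(
                "load_log10_by_segment: one value per segment required"
            )
        if not 0 <= self.unsaturated_fraction <= 1:
            raise ConfigurationError("unsaturated_fraction: must lie in [0, 1]")
        if self.depth_range[0] > self.depth_range[1]:
            raise ConfigurationError("depth_range: lower bound exceeds upper bound")

    def with_(self, **kwargs) -> "CohortConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def canonical_site(name: str) -> str:
    """Map a site alias to the controlled vocabulary; pass through known names."""
    key = name.strip().lower()
    if key in SEGMENTS or key in COMPARTMENTS:
        return key
    if key in SITE_ALIASES:
        return SITE_ALIASES[key]
    raise ConfigurationError(f"unknown site name {name!r}")
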