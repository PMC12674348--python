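"""Synthetic multi-omics cohort generator with known planted effects.

Every layer of the emulated study — sample metadata, host phenotypes,
per-segment taxonomic profiles, per-compartment metabolomes, rarefaction
curves and qPCR plates — is generated from explicit ground truth so that
each downstream statistical stage can be verified against what was planted.

Design notes
------------
* Taxon profiles are logistic-normal: Gaussian log-abundances exponentiated
  and closed to 100 percent, with zeros introduced by a detection threshold.
* A planted Cliff's delta is realised as a latent location shift through the
  Gaussian link ``delta = 2 * Phi(mu / (sqrt(2) * sigma)) - 1``, which is
  monotone and invertible, so calibration tests can recover the target.
* The proximal (small intestine) and distal (colon/feces) segments use
  distinct centroid families: distal-restricted taxa (Bacteroidota-like)
  carry a latent deficit in proximal segments, mirroring the strong
  proximal/distal clustering seen in real gut surveys.
* All randomness flows from ``config.seed`` through fixed per-stage
  substreams, so each generator is individually deterministic and the
  taxon latent noise reused by the metabolome copula is identical whether
  the generators are called together or standalone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import (
    COMPARTMENTS,
    DIETS,
    SEGMENTS,
    SEXES,
    SMALL_INTESTINE,
    CohortConfig,
    ConfigurationError,
    CorrelatedPair,
    PlantedEffect,
)
from .preprocess import RarefactionCurve

__all__ = [
    "SyntheticCohort",
    "build_taxonomy",
    "default_config",
    "default_effect_table",
    "default_correlated_pairs",
    "generate_cohort",
    "generate_taxon_profiles",
    "generate_metabolomes",
    "generate_rarefaction_curves",
    "generate_qpcr",
    "profile_to_counts",
    "simulate_cohort",
]

# fixed substream tags so standalone generator calls stay mutually consistent
_STAGE = {
    "cohort": 11,
    "taxa": 12,
    "taxa_noise": 13,
    "metabolome": 14,
    "rarefaction": 15,
    "qpcr": 16,
}


def _rng(config: CohortConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage]])


def delta_to_shift(delta: float, sigma: float) -> float:
    """Latent location shift realising a target Cliff's delta.

    Inverts ``delta = 2 * Phi(mu / (sqrt(2) * sigma)) - 1``, the exact
    relation between the delta of two equal-variance Gaussians and their
    mean difference ``mu``.
    """
    return float(np.sqrt(2.0) * sigma * norm.ppf((delta + 1.0) / 2.0))


# --------------------------------------------------------------------------
# taxonomy
# --------------------------------------------------------------------------

# (kingdom, phylum, class, order, family, genus, distal_restricted, dominance)
_GENUS_TABLE = [
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus", False, 3.0),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Ligilactobacillus", False, 1.5),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Limosilactobacillus", False, 1.0),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus", False, 1.0),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Enterococcaceae", "Enterococcus", False, 1.0),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Blautia", True, 1.0),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Roseburia", True, 1.0),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Lachnospiraceae", "Coprococcus", True, 0.5),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae", "Oscillibacter", True, 0.5),
    ("Bacteria", "Firmicutes", "Clostridia", "Eubacteriales", "Oscillospiraceae", "Faecalibacterium", True, 1.0),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella", False, 1.5),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Megasphaera", False, 0.0),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Dialister", False, 0.0),
    ("Bacteria", "Actinobacteriota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium", False, 0.5),
    ("Bacteria", "Actinobacteriota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Pseudoscardovia", False, 0.0),
    ("Bacteria", "Actinobacteriota", "Actinomycetia", "Bifidobacteriales", "Bifidobacteriaceae", "Aeriscardovia", False, 0.0),
    ("Bacteria", "Actinobacteriota", "Actinomycetia", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium", False, 1.0),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides", True, 2.0),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella", True, 2.0),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Segatella", True, 1.0),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia", False, 0.5),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Klebsiella", False, 0.0),
    ("Bacteria", "Spirochaetota", "Spirochaetia", "Treponematales", "Treponemataceae", "Treponema", True, 0.5),
    ("Archaea", "Euryarchaeota", "Methanobacteria", "Methanobacteriales", "Methanobacteriaceae", "Methanobrevibacter", True, 0.0),
]

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


def build_taxonomy(n_taxa: int):
    """Deterministic synthetic species catalogue.

    Species are dealt round-robin across a fixed genus table so that every
    genus owns several species (needed by the lineage-aggregation and
    forest-plot stages).  Returns ``(lineages, distal_mask, dominance)``
    where ``lineages`` are 7-rank pipe-delimited strings, ``distal_mask``
    marks taxa restricted to the distal gut and ``dominance`` is a latent
    baseline boost making a few families dominate, as in real profiles.
    """
    lineages, distal, dominance = [], [], []
    counters = {row[5]: 0 for row in _GENUS_TABLE}
    for i in range(n_taxa):
        row = _GENUS_TABLE[i % len(_GENUS_TABLE)]
        k, p, c, o, f, g, is_distal, dom = row
        counters[g] += 1
        species = f"{g}_sp{counters[g]}"
        parts = (k, p, c, o, f, g, species)
        lineages.append("|".join(pref + name for pref, name in zip(_RANK_PREFIXES, parts)))
        distal.append(is_distal)
        # only the first species of a genus carries the full dominance boost
        dominance.append(dom if counters[g] == 1 else dom * 0.3)
    return lineages, np.asarray(distal), np.asarray(dominance)


def species_lineage(genus: str, n_taxa: int = 150, nth: int = 1) -> str:
    """Lineage string of the nth generated species of ``genus``."""
    lineages, _, _ = build_taxonomy(n_taxa)
    suffix = f"|g__{genus}|s__{genus}_sp{nth}"
    for lin in lineages:
        if lin.endswith(suffix):
            return lin
    raise ConfigurationError(f"no species of genus {genus!r} among {n_taxa} taxa")


# --------------------------------------------------------------------------
# metabolite catalogue
# --------------------------------------------------------------------------

METABOLITE_CLASSES = (
    "triacylglycerols",
    "diacylglycerols",
    "phosphatidylcholines",
    "phosphatidylserines",
    "phosphatidic_acids",
    "ceramides",
    "bile_acids",
    "amino_acids",
    "biogenic_amines",
    "indole_derivatives",
    "alkaloids",
    "cresols",
)


def build_metabolite_catalogue(n_metabolites: int) -> pd.DataFrame:
    """Metabolite ids with class labels, dealt round-robin over the classes."""
    ids, classes = [], []
    counters = {c: 0 for c in METABOLITE_CLASSES}
    for i in range(n_metabolites):
        cls = METABOLITE_CLASSES[i % len(METABOLITE_CLASSES)]
        counters[cls] += 1
        ids.append(f"{cls}_{counters[cls]:02d}")
        classes.append(cls)
    return pd.DataFrame({"metabolite_id": ids, "class": classes}).set_index("metabolite_id")


# --------------------------------------------------------------------------
# default study conditions
# --------------------------------------------------------------------------

#: phenotype -> (female mean, male mean, coefficient of variation); units as
#: in the emulated trial (kg, mg/dL, µU/mL, mmol/L, µg/mL, ng/g).
PHENOTYPE_BASELINES = {
    "body_weight": (62.0, 69.0, 0.12),
    "fasting_glucose": (105.0, 108.0, 0.12),
    "fasting_insulin": (7.5, 8.3, 0.35),
    "triglycerides": (50.0, 63.0, 0.30),
    "total_cholesterol": (104.0, 116.0, 0.12),
    "hdl_cholesterol": (41.0, 58.0, 0.12),
    "ldl_cholesterol": (52.0, 55.0, 0.22),
    "nefa": (0.21, 0.23, 0.45),
    "urea": (31.0, 34.0, 0.22),
    "crp": (10.0, 6.0, 0.50),
    "lipocalin2_dj": (43.0, 41.0, 0.90),
    "lipocalin2_feces": (46.0, 49.0, 0.80),
}


def default_effect_table(n_taxa: int = 150) -> tuple:
    """Planted effects emulating the reported diet x sex x site signals.

    Positive delta / multiplier > 1 means higher under the medium-fat diet.
    The pattern includes both-sex effects, sex-specific effects and one
    taxon with opposite sign in proximal vs distal segments.
    """
    sp = lambda genus: species_lineage(genus, n_taxa)
    t = lambda fid, delta, *strata: PlantedEffect(fid, "taxon", tuple(strata), delta)
    m = lambda fid, mult, *strata: PlantedEffect(fid, "metabolite", tuple(strata), mult, mode="multiplier")
    return (
        # taxa
        t(sp("Lactobacillus"), -0.8, (None, "jejunum")),
        t(sp("Ligilactobacillus"), -0.7, (None, "duodenojejunum")),
        t(sp("Limosilactobacillus"), -0.7, (None, "jejunum")),
        t(sp("Bifidobacterium"), 0.7, (None, "jejunum")),
        t(sp("Pseudoscardovia"), 0.8, (None, "duodenojejunum")),
        t(sp("Streptococcus"), 0.8, ("female", "jejunum")),
        t(sp("Megasphaera"), 0.6, ("male", "jejunum")),
        t(sp("Megasphaera"), -0.6, ("male", "feces")),
        t(sp("Roseburia"), -0.6, (None, "proximal_colon"), (None, "feces")),
        t(sp("Escherichia"), -0.8, (None, "duodenojejunum")),
        # metabolite classes
        m("class:triacylglycerols", 2.0, (None, "dj_fluid")),
        m("class:phosphatidic_acids", 1.6, (None, "dj_fluid")),
        m("class:alkaloids", 0.5, (None, "dj_fluid")),
        m("class:bile_acids", 0.5, ("male", "bile")),
        m("class:phosphatidylserines", 0.6, ("female", "bile")),
        # host phenotypes
        PlantedEffect("hdl_cholesterol", "phenotype", ((None, None),), 1.3, mode="multiplier"),
        PlantedEffect("crp", "phenotype", (("female", None),), 1.5, mode="multiplier"),
        # bacterial load (female-specific depletion distally)
        PlantedEffect("jejunum", "load", (("female", "jejunum"),), 0.3, mode="multiplier"),
        PlantedEffect("proximal_colon", "load", (("female", "proximal_colon"),), 0.4, mode="multiplier"),
        PlantedEffect("feces", "load", (("female", "feces"),), 0.5, mode="multiplier"),
    )


def default_correlated_pairs(n_taxa: int = 150) -> tuple:
    """Taxon-metabolite pairs generated with a true rank correlation."""
    return (
        CorrelatedPair(species_lineage("Veillonella", n_taxa), "duodenojejunum", "amino_acids_01", "dj_fluid", 0.7),
        CorrelatedPair(species_lineage("Enterococcus", n_taxa), "jejunum", "indole_derivatives_01", "dj_fluid", 0.7),
        CorrelatedPair(species_lineage("Corynebacterium", n_taxa), "duodenojejunum", "bile_acids_01", "bile", -0.6),
    )


def default_config(seed: int = 0, **overrides) -> CohortConfig:
    """The default synthetic study: sizes, planted effects and seeds."""
    n_taxa = int(overrides.pop("n_taxa", 150))
    cfg = CohortConfig(
        seed=seed,
        n_taxa=n_taxa,
        effect_table=default_effect_table(n_taxa),
        correlated_pairs=default_correlated_pairs(n_taxa),
        **overrides,
    )
    return cfg


# --------------------------------------------------------------------------
# cohort metadata + phenotypes
# --------------------------------------------------------------------------


def _pig_table(config: CohortConfig) -> pd.DataFrame:
    rows = []
    for sex, diet in itertools.product(SEXES, DIETS):
        for i in range(config.n_per_group):
            pig = f"{sex[0].upper()}{diet}{i + 1:02d}"
            rows.append({"pig_id": pig, "sex": sex, "diet": diet})
    return pd.DataFrame(rows)


def _effect_applies(effect: PlantedEffect, sex: str, site) -> bool:
    for s_sex, s_site in effect.strata:
        if (s_sex is None or s_sex == sex) and (s_site is None or s_site == site):
            return True
    return False


def generate_cohort(config: CohortConfig):
    """Generate sample metadata and host phenotypes.

    Returns ``(samples, phenotypes)``: one metagenome sample per pig per
    segment plus one metabolome sample per pig per compartment, and one
    phenotype record per pig drawn from sex-specific log-normal baselines
    with any planted diet shifts applied on the log scale.
    """
    pigs = _pig_table(config)
    rows = []
    for _, p in pigs.iterrows():
        for seg in config.segments:
            rows.append({**p, "site": seg, "layer": "metagenome",
                         "sample_id": f"{p.pig_id}_{seg}"})
        for comp in config.compartments:
            rows.append({**p, "site": comp, "layer": "metabolome",
                         "sample_id": f"{p.pig_id}_{comp}"})
    samples = pd.DataFrame(rows, columns=["sample_id", "pig_id", "sex", "diet", "site", "layer"])

    rng = _rng(config, "cohort")
    pheno_effects = [e for e in config.effect_table if e.layer == "phenotype"]
    known = set(PHENOTYPE_BASELINES)
    for e in pheno_effects:
        if e.feature_id not in known:
            raise ConfigurationError(f"effect on unknown phenotype {e.feature_id!r}")

    data = {"pig_id": pigs.pig_id, "sex": pigs.sex, "diet": pigs.diet}
    for name, (mu_f, mu_m, cv) in PHENOTYPE_BASELINES.items():
        sd_log = np.sqrt(np.log1p(cv**2))
        mean = np.where(pigs.sex == "female", mu_f, mu_m).astype(float)
        log_val = np.log(mean) - sd_log**2 / 2 + sd_log * rng.standard_normal(len(pigs))
        for e in pheno_effects:
            if e.feature_id != name:
                continue
            mask = (pigs.diet == "MFD").to_numpy() & np.fromiter(
                (_effect_applies(e, s, None) for s in pigs.sex), bool, len(pigs)
            )
            shift = (np.log(e.effect_size) if e.mode == "multiplier"
                     else delta_to_shift(e.effect_size, sd_log))
            log_val = np.where(mask, log_val + shift, log_val)
        data[name] = np.exp(log_val)
    phenotypes = pd.DataFrame(data)
    return samples, phenotypes


# --------------------------------------------------------------------------
# taxon profiles
# --------------------------------------------------------------------------


def _logsumexp_cols(latent: np.ndarray) -> np.ndarray:
    m = latent.max(axis=0, keepdims=True)
    return m + np.log(np.exp(latent - m).sum(axis=0, keepdims=True))


def _taxon_noise(samples: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Standard-normal latent noise, taxa x metagenome samples.

    Drawn from its own substream so the metabolome copula can reproduce it
    without the profiles being generated first.
    """
    meta = samples[samples.layer == "metagenome"]
    rng = _rng(config, "taxa_noise")
    z = rng.standard_normal((config.n_taxa, len(meta)))
    lineages, _, _ = build_taxonomy(config.n_taxa)
    return pd.DataFrame(z, index=lineages, columns=meta.sample_id.to_numpy())


def generate_taxon_profiles(samples: pd.DataFrame, config: CohortConfig):
    """Per-segment relative-abundance matrices with ground truth.

    Returns ``(profiles, truth)`` where ``profiles`` maps segment name to a
    taxa x samples DataFrame of percentages closing to 100, and ``truth``
    lists the realised target delta for every feature x (sex, segment)
    stratum (0 for nulls).
    """
    lineages, distal_mask, dominance = build_taxonomy(config.n_taxa)
    lineage_set = set(lineages)
    effects = [e for e in config.effect_table if e.layer == "taxon"]
    for e in effects:
        if e.feature_id not in lineage_set:
            raise ConfigurationError(f"effect on unknown taxon {e.feature_id!r}")

    rng = _rng(config, "taxa")
    n = config.n_taxa
    base = dominance * config.centroid_sigma + rng.normal(0.0, config.centroid_sigma, n)
    # family-level centroids: distal-restricted taxa suppressed proximally,
    # plus a family-specific re-draw so the two families genuinely differ
    family_jitter = {
        "proximal": rng.normal(0.0, 0.7, n),
        "distal": rng.normal(0.0, 0.7, n),
    }
    seg_jitter = {seg: rng.normal(0.0, 0.3, n) for seg in config.segments}

    noise = _taxon_noise(samples, config)
    meta = samples[samples.layer == "metagenome"].set_index("sample_id")

    profiles = {}
    for seg in config.segments:
        fam = "proximal" if seg in SMALL_INTESTINE else "distal"
        centroid = base + family_jitter[fam] + seg_jitter[seg]
        if fam == "proximal":
            centroid = centroid - config.distal_shift * distal_mask
        cols = meta.index[meta.site == seg]
        z = noise[cols].to_numpy()
        latent = centroid[:, None] + config.latent_sigma * z
        # Planted diet shifts on the latent scale.  A target delta is mapped
        # through the Gaussian link against the realised log relative
        # abundance SD of the stratum (latent noise + closure noise), not
        # the latent sigma alone: closure adds sample-to-sample log-total
        # variation that would otherwise attenuate the realised delta.
        log_rel0 = latent - _logsumexp_cols(latent)
        sexes = meta.loc[cols, "sex"].to_numpy()
        diets = meta.loc[cols, "diet"].to_numpy()
        for e in effects:
            idx = lineages.index(e.feature_id)
            for sex in SEXES:
                if not _effect_applies(e, sex, seg):
                    continue
                stratum = sexes == sex
                if e.mode == "multiplier":
                    shift = np.log(e.effect_size)
                else:
                    s_obs = float(np.std(log_rel0[idx, stratum]))
                    shift = delta_to_shift(e.effect_size,
                                           max(s_obs, 1e-6))
                latent[idx, stratum & (diets == "MFD")] += shift
        ab = np.exp(latent - latent.max(axis=0, keepdims=True))
        ab = 100.0 * ab / ab.sum(axis=0, keepdims=True)
        ab[ab < config.detection_limit] = 0.0
        ab = 100.0 * ab / ab.sum(axis=0, keepdims=True)
        profiles[seg] = pd.DataFrame(ab, index=lineages, columns=cols)

    truth = _truth_table(lineages, config.segments, effects)
    return profiles, truth


def _truth_table(feature_ids, sites, effects, class_members=None) -> pd.DataFrame:
    rows = []
    for fid in feature_ids:
        for sex in SEXES:
            for site in sites:
                eff = 0.0
                mode = "delta"
                for e in effects:
                    target = e.feature_id
                    if class_members is not None and target.startswith("class:"):
                        if fid not in class_members.get(target[6:], ()):
                            continue
                    elif target != fid:
                        continue
                    if _effect_applies(e, sex, site):
                        eff = e.effect_size
                        mode = e.mode
                rows.append({"feature_id": fid, "sex": sex, "site": site,
                             "true_effect": eff, "mode": mode,
                             "is_null": eff == 0.0 or (mode == "multiplier" and eff == 1.0)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# metabolomes
# --------------------------------------------------------------------------


def generate_metabolomes(samples: pd.DataFrame, config: CohortConfig):
    """Per-compartment concentration matrices with class labels and truth.

    Concentrations are log-normal around class- and compartment-specific
    baselines.  Planted class shifts multiply all member metabolites in MFD
    samples of the targeted strata.  Configured taxon-metabolite pairs share
    a Gaussian copula with the normal scores of the matched pig's realised
    taxon abundance, yielding a chosen true Spearman correlation (the latent
    Pearson r uses the bivariate-normal conversion
    ``r = 2 sin(pi * rho_s / 6)``); coupling to the observed abundance
    rather than its latent noise keeps the target from being attenuated by
    compositional closure.
    """
    catalogue = build_metabolite_catalogue(config.n_metabolites)
    met_ids = list(catalogue.index)
    class_members = {
        cls: set(catalogue.index[catalogue["class"] == cls])
        for cls in METABOLITE_CLASSES
    }
    effects = [e for e in config.effect_table if e.layer == "metabolite"]
    for e in effects:
        fid = e.feature_id
        if fid.startswith("class:"):
            if fid[6:] not in class_members:
                raise ConfigurationError(f"effect on unknown metabolite class {fid[6:]!r}")
        elif fid not in catalogue.index:
            raise ConfigurationError(f"effect on unknown metabolite {fid!r}")

    rng = _rng(config, "metabolome")
    n_met = config.n_metabolites
    class_mu = {cls: rng.normal(3.0, 1.0) for cls in METABOLITE_CLASSES}
    met_mu = np.array([class_mu[c] for c in catalogue["class"]]) + rng.normal(0.0, 0.5, n_met)
    comp_offset = {comp: rng.normal(0.0, 0.5, n_met) for comp in config.compartments}

    meta = samples[samples.layer == "metabolome"].set_index("sample_id")
    profiles = (generate_taxon_profiles(samples, config)[0]
                if config.correlated_pairs else None)

    out = {}
    for comp in config.compartments:
        cols = meta.index[meta.site == comp]
        z = rng.standard_normal((n_met, len(cols)))
        # copula-coupled pairs: blend the metabolite's noise with the normal
        # scores of the matched pig's realised taxon abundance
        for pair in config.correlated_pairs:
            if pair.compartment != comp:
                continue
            if pair.metabolite_id not in catalogue.index:
                raise ConfigurationError(f"correlated pair on unknown metabolite {pair.metabolite_id!r}")
            r = 2.0 * np.sin(np.pi * pair.rho / 6.0)
            mi = met_ids.index(pair.metabolite_id)
            pigs = meta.loc[cols, "pig_id"]
            tax_vals = profiles[pair.taxon_site].loc[
                pair.taxon_id, [f"{pig}_{pair.taxon_site}" for pig in pigs]
            ].to_numpy(dtype=float)
            zt = norm.ppf((rankdata(tax_vals) - 0.5) / len(tax_vals))
            z[mi, :] = r * zt + np.sqrt(1.0 - r**2) * z[mi, :]
        latent = met_mu[:, None] + comp_offset[comp][:, None] + config.metabolome_sigma * z
        for e in effects:
            if e.feature_id.startswith("class:"):
                rows_idx = [i for i, c in enumerate(catalogue["class"]) if c == e.feature_id[6:]]
            else:
                rows_idx = [met_ids.index(e.feature_id)]
            shift = (np.log(e.effect_size) if e.mode == "multiplier"
                     else delta_to_shift(e.effect_size, config.metabolome_sigma))
            for j, sid in enumerate(cols):
                row = meta.loc[sid]
                if row.diet == "MFD" and _effect_applies(e, row.sex, comp):
                    latent[rows_idx, j] += shift
        out[comp] = pd.DataFrame(np.exp(latent), index=met_ids, columns=cols)

    truth = _truth_table(met_ids, config.compartments, effects,
                         class_members=class_members)
    return out, truth, catalogue


# --------------------------------------------------------------------------
# rarefaction curves
# --------------------------------------------------------------------------


def generate_rarefaction_curves(samples: pd.DataFrame, config: CohortConfig):
    """Saturating marker-discovery curves, one per metagenome sample.

    Expected discovery follows ``M(d) = M_pool * (1 - exp(-d / d0))``; a
    configurable fraction of samples is sequenced shallowly, leaving them on
    the steep part of the curve so the end-slope QC rule has true positives.
    """
    if config.n_curve_points < 2:
        raise ConfigurationError("n_curve_points: need at least 2 points per curve")
    rng = _rng(config, "rarefaction")
    meta = samples[samples.layer == "metagenome"]
    curves = []
    for sid in meta.sample_id:
        shallow = rng.random() < config.unsaturated_fraction
        lo, hi = (config.unsaturated_depth_range if shallow else config.depth_range)
        depth = rng.uniform(lo, hi)
        grid = np.linspace(depth / config.n_curve_points, depth, config.n_curve_points)
        depths = np.round(grid).astype(np.int64)
        markers = np.round(
            config.marker_pool * (1.0 - np.exp(-depths / config.discovery_scale))
        ).astype(np.int64)
        markers = np.maximum.accumulate(markers)
        curves.append(RarefactionCurve(sid, depths, markers))
    return curves


# --------------------------------------------------------------------------
# qPCR plates
# --------------------------------------------------------------------------


def generate_qpcr(samples: pd.DataFrame, config: CohortConfig):
    """Simulated qPCR plate with standards and the latent loads.

    Latent 16S copies per gram follow the configured proximal-to-distal
    log10 gradient with log-normal pig-to-pig scatter and any planted load
    shifts; Ct values are generated from the plate's standard curve.
    Returns ``(ct_table, standards, load_truth)`` — the third element is the
    generator's ground truth, not an instrument output.
    """
    seg_log10 = dict(zip(config.segments, config.load_log10_by_segment))
    effects = [e for e in config.effect_table if e.layer == "load"]
    for e in effects:
        if e.feature_id not in seg_log10:
            raise ConfigurationError(f"load effect on unknown segment {e.feature_id!r}")

    rng = _rng(config, "qpcr")
    meta = samples[samples.layer == "metagenome"]
    rows, truth_rows = [], []
    for _, s in meta.iterrows():
        log10_load = seg_log10[s.site] + rng.normal(0.0, config.load_log10_sd)
        for e in effects:
            if e.feature_id == s.site and s.diet == "MFD" and _effect_applies(e, s.sex, s.site):
                log10_load += (np.log10(e.effect_size) if e.mode == "multiplier"
                               else delta_to_shift(e.effect_size, config.load_log10_sd))
        if log10_load <= -12:  # pragma: no cover - guards absurd configs
            raise ConfigurationError(f"nonpositive latent load for {s.sample_id}")
        copies_g = 10.0**log10_load
        mass_mg = 400.0 if s.site in SMALL_INTESTINE else 150.0
        copies_rxn = copies_g * (mass_mg / 1000.0) / config.dilution_factor
        ct = (config.qpcr_intercept + config.qpcr_slope * np.log10(copies_rxn)
              + rng.normal(0.0, config.qpcr_ct_noise))
        rows.append({"sample_id": s.sample_id, "ct": ct,
                     "dilution_factor": config.dilution_factor, "mass_mg": mass_mg})
        truth_rows.append({"sample_id": s.sample_id, "site": s.site, "sex": s.sex,
                           "diet": s.diet, "copies_per_gram": copies_g})
    log10_std = np.arange(2.0, 9.0)
    std = pd.DataFrame({
        "log10_copies": log10_std,
        "ct": config.qpcr_intercept + config.qpcr_slope * log10_std
        + rng.normal(0.0, config.qpcr_ct_noise, len(log10_std)),
    })
    return pd.DataFrame(rows), std, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# counts bridge + bundle
# --------------------------------------------------------------------------


def profile_to_counts(profiles: pd.DataFrame, depths, seed: int) -> pd.DataFrame:
    """Draw integer feature counts from relative abundances.

    ``depths`` maps sample id to the number of counted units; each sample is
    a multinomial draw with probabilities proportional to its profile.
    """
    rng = np.random.default_rng(seed)
    counts = {}
    for sid in profiles.columns:
        p = profiles[sid].to_numpy(dtype=float)
        p = p / p.sum()
        counts[sid] = rng.multinomial(int(depths[sid]), p)
    return pd.DataFrame(counts, index=profiles.index)


@dataclass
class SyntheticCohort:
    """Bundle of all generated layers plus their ground truth."""

    config: CohortConfig
    samples: pd.DataFrame
    phenotypes: pd.DataFrame
    taxon_profiles: dict
    taxon_truth: pd.DataFrame
    metabolomes: dict
    metabolite_truth: pd.DataFrame
    class_map: pd.DataFrame
    rarefaction_curves: list
    qpcr_ct: pd.DataFrame
    qpcr_standards: pd.DataFrame
    load_truth: pd.DataFrame


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Run every generator stage under one configuration."""
    config = config if config is not None else default_config()
    samples, phenotypes = generate_cohort(config)
    profiles, taxon_truth = generate_taxon_profiles(samples, config)
    metabolomes, met_truth, class_map = generate_metabolomes(samples, config)
    curves = generate_rarefaction_curves(samples, config)
    ct, standards, load_truth = generate_qpcr(samples, config)
    return SyntheticCohort(config, samples, phenotypes, profiles, taxon_truth,
                           metabolomes, met_truth, class_map, curves, ct,
                           standards, load_truth)
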