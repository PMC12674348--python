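"""Pipeline driver: simulate -> qc -> diversity -> differential -> crossomics.

Each stage reads the outputs of its predecessors from the run directory,
writes provenance-stamped TSVs, and appends counts (samples excluded by
QC, strata skipped, records written) to the run log.  All randomness is
derived from the single master seed through named substreams, so a rerun
with the same configuration and seed reproduces every output byte for
byte.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crossomics as xo
from . import differential as diff
from . import diversity as div
from . import io as gio
from . import preprocess as pre
from . import simulate as sim
from .config import COMPARTMENTS, DIETS, SEGMENTS, SEXES, ConfigurationError

logger = logging.getLogger("gutomics")

#: metabolite classes flagged as linked to bacterial metabolism in the
#: example annotation map shipped with the synthetic cohort
BACTERIAL_CLASSES = (
    "bile_acids", "indole_derivatives", "biogenic_amines",
    "amino_acids", "cresols", "alkaloids",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "gutomics_run"
    seed: int = 0
    n_perm: int = 2000
    n_boot: int = 1000
    alpha: float = 0.05
    qc_threshold: float = pre.DEFAULT_QC_THRESHOLD
    metabolite_scale: str = "zlog"
    fdr_scope: str = "stratum"
    taxon_ranks: tuple = ("species", "genus", "family", "phylum")
    n_top_genera: int = 30
    permanova_permutations: int = 999
    simulate: bool = True
    # optional external inputs (used when simulate is False)
    profile_paths: dict = field(default_factory=dict)  # segment -> TSV
    metabolome_paths: dict = field(default_factory=dict)  # compartment -> CSV
    class_map_path: str | None = None
    metadata_path: str | None = None
    phenotype_path: str | None = None
    rarefaction_path: str | None = None
    qpcr_ct_path: str | None = None
    qpcr_standards_path: str | None = None
    cohort_overrides: dict = field(default_factory=dict)

    def digest(self) -> str:
        # the output location is not part of the analysis configuration
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return gio.config_digest(d)


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration, checking referenced paths exist."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**data)
    _check_paths(cfg)
    return cfg


def _check_paths(cfg: RunConfig) -> None:
    paths = list(cfg.profile_paths.values()) + list(cfg.metabolome_paths.values())
    paths += [p for p in (cfg.class_map_path, cfg.metadata_path, cfg.phenotype_path,
                          cfg.rarefaction_path, cfg.qpcr_ct_path,
                          cfg.qpcr_standards_path) if p]
    missing = [p for p in paths if not Path(p).exists()]
    if missing:
        raise ConfigurationError(f"input path(s) do not exist: {missing}")


def _stage_seed(master: int, stage: str) -> np.random.SeedSequence:
    tag = int.from_bytes(stage.encode()[:4].ljust(4, b"\0"), "big")
    return np.random.SeedSequence([int(master), tag])


def _stage_int(master: int, stage: str) -> int:
    return int(_stage_seed(master, stage).generate_state(1)[0] % (2**31))


class PipelineData:
    """In-memory carrier of the tables flowing between stages."""

    def __init__(self):
        self.samples = None
        self.phenotypes = None
        self.profiles = {}
        self.metabolomes = {}
        self.class_map = None
        self.curves = []
        self.qpcr_ct = None
        self.qpcr_standards = None
        self.kept_samples = None
        self.segment_depths = None
        self.counts = {}
        self.taxon_screen = None
        self.metabolite_screen = None


def run_pipeline(cfg: RunConfig,
                 stages=("simulate", "qc", "diversity", "differential",
                         "crossomics")) -> Path:
    """Execute the requested stages; returns the output directory."""
    _check_paths(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    data = PipelineData()
    try:
        logger.info("run start: seed=%d config=%s", cfg.seed, cfg.digest())
        if "simulate" in stages and cfg.simulate:
            _stage_simulate(cfg, data, out)
        else:
            _load_inputs(cfg, data)
        for stage, fn in (("qc", _stage_qc), ("diversity", _stage_diversity),
                          ("differential", _stage_differential),
                          ("crossomics", _stage_crossomics)):
            if stage in stages:
                try:
                    fn(cfg, data, out)
                except Exception as exc:
                    raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        logger.info("run complete")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _writer(cfg: RunConfig):
    digest = cfg.digest()

    def write(df, path, **kw):
        gio.write_table(df, path, seed=cfg.seed, config_hash=digest, **kw)

    return write


def _stage_simulate(cfg: RunConfig, data: PipelineData, out: Path) -> None:
    ccfg = sim.default_config(seed=_stage_int(cfg.seed, "sim"),
                              **cfg.cohort_overrides)
    cohort = sim.simulate_cohort(ccfg)
    data.samples = cohort.samples
    data.phenotypes = cohort.phenotypes
    data.profiles = cohort.taxon_profiles
    data.metabolomes = cohort.metabolomes
    data.class_map = cohort.class_map["class"]
    data.curves = cohort.rarefaction_curves
    data.qpcr_ct = cohort.qpcr_ct
    data.qpcr_standards = cohort.qpcr_standards

    d = out / "inputs"
    digest = cfg.digest()
    gio.write_metadata(cohort.samples, d / "samples.csv", cfg.seed, digest)
    gio.write_table(cohort.phenotypes, d / "phenotypes.csv", cfg.seed, digest,
                    sep=",", index=False)
    for seg, prof in cohort.taxon_profiles.items():
        gio.write_profiles(prof, d / f"profiles_{seg}.tsv", cfg.seed, digest)
    for comp, met in cohort.metabolomes.items():
        gio.write_metabolites(met, d / f"metabolome_{comp}.csv", cfg.seed, digest)
    cm = cohort.class_map.reset_index()
    gio.write_table(cm, d / "metabolite_classes.csv", cfg.seed, digest,
                    sep=",", index=False)
    gio.write_rarefaction(cohort.rarefaction_curves, d / "rarefaction.tsv",
                          cfg.seed, digest)
    gio.write_qpcr(cohort.qpcr_ct, cohort.qpcr_standards, d / "qpcr_ct.tsv",
                   d / "qpcr_standards.tsv", cfg.seed, digest)
    gio.write_table(cohort.taxon_truth, d / "taxon_truth.tsv", cfg.seed, digest,
                    index=False)
    gio.write_table(cohort.metabolite_truth, d / "metabolite_truth.tsv",
                    cfg.seed, digest, index=False)
    logger.info("simulate: %d pigs, %d samples", cohort.phenotypes.shape[0],
                cohort.samples.shape[0])


def _load_inputs(cfg: RunConfig, data: PipelineData) -> None:
    if cfg.metadata_path is None:
        raise ConfigurationError("metadata_path required when simulate is off")
    data.samples = gio.read_metadata(cfg.metadata_path)
    if cfg.phenotype_path:
        data.phenotypes = pd.read_csv(cfg.phenotype_path, comment="#")
    for seg, path in cfg.profile_paths.items():
        data.profiles[seg] = gio.read_profiles(path)
    for comp, path in cfg.metabolome_paths.items():
        matrix, classes, _ = gio.read_metabolites(path, cfg.class_map_path)
        data.metabolomes[comp] = matrix
        data.class_map = classes
    if cfg.rarefaction_path:
        data.curves = gio.read_rarefaction(cfg.rarefaction_path)
    if cfg.qpcr_ct_path and cfg.qpcr_standards_path:
        data.qpcr_ct, data.qpcr_standards = gio.read_qpcr(
            cfg.qpcr_ct_path, cfg.qpcr_standards_path)


def _meta_indexed(data: PipelineData) -> pd.DataFrame:
    return data.samples.set_index("sample_id")


def _stage_qc(cfg: RunConfig, data: PipelineData, out: Path) -> None:
    write = _writer(cfg)
    decisions = pre.qc_filter(data.curves, threshold=cfg.qc_threshold)
    table = pre.qc_table(decisions)
    write(table, out / "qc" / "decisions.tsv", index=False)
    kept = set(table.sample_id[table.kept])
    data.kept_samples = kept
    logger.info("qc: %d/%d samples kept (threshold %.3f)",
                len(kept), len(table), cfg.qc_threshold)

    meta = _meta_indexed(data)
    depths = pd.Series({c.sample_id: c.final_depth for c in data.curves})
    segments = meta.loc[depths.index, "site"]
    data.segment_depths = pre.segment_depth_policy(depths, segments, kept)
    write(pd.DataFrame({"segment": list(data.segment_depths),
                        "target_depth": list(data.segment_depths.values())}),
          out / "qc" / "segment_depths.tsv", index=False)

    if data.qpcr_ct is not None:
        curve = pre.fit_standard_curve(data.qpcr_standards["log10_copies"],
                                       data.qpcr_standards["ct"])
        loads = pre.qpcr_load_table(data.qpcr_ct, curve)
        write(pd.DataFrame([{"slope": curve.slope, "intercept": curve.intercept,
                             "r_squared": curve.r_squared}]),
              out / "qc" / "standard_curve.tsv", index=False)
        write(loads, out / "qc" / "bacterial_load.tsv", index=False)
        data.loads = loads

    if data.phenotypes is not None and {
        "fasting_insulin", "fasting_glucose"}.issubset(data.phenotypes.columns):
        ph = data.phenotypes.copy()
        ph["homa_ir"] = pre.homa_ir(ph["fasting_insulin"], ph["fasting_glucose"])
        data.phenotypes = ph
        write(ph, out / "qc" / "phenotypes_derived.csv", sep=",", index=False)


def _kept_profiles(data: PipelineData) -> dict:
    kept = data.kept_samples or set()
    return {
        seg: prof.loc[:, [c for c in prof.columns if c in kept]]
        for seg, prof in data.profiles.items()
    }


def _stage_diversity(cfg: RunConfig, data: PipelineData, out: Path) -> None:
    write = _writer(cfg)
    meta = _meta_indexed(data)
    profiles = _kept_profiles(data)
    depths = {c.sample_id: int(c.final_depth) for c in data.curves}

    alpha_frames, fc_frames, fc_tests, perma_rows = [], [], [], []
    pooled = []
    for seg, prof in profiles.items():
        if prof.shape[1] == 0:
            logger.warning("diversity: segment %s empty after QC", seg)
            continue
        counts = sim.profile_to_counts(
            prof, depths, _stage_int(cfg.seed, f"cnt_{seg}"))
        rarefied = pre.rarefy_matrix(counts, data.segment_depths[seg],
                                     _stage_int(cfg.seed, f"rar_{seg}"))
        data.counts[seg] = rarefied
        alpha = div.alpha_indices(rarefied)
        alpha.insert(0, "segment", seg)
        alpha_frames.append(alpha)
        for index_name in ("richness", "shannon", "simpson", "evenness"):
            vals = alpha[index_name].dropna()
            if vals.empty:
                continue
            fc, tests = div.alpha_log2fc(vals, meta)
            frame = fc.to_frame("log2fc").assign(segment=seg, index=index_name)
            frame = frame.join(meta[["sex", "diet"]])
            fc_frames.append(frame.reset_index(names="sample_id"))
            fc_tests.append(tests.reset_index().assign(segment=seg,
                                                       index=index_name))
        bc = div.bray_curtis(prof)
        groups = (meta.loc[list(bc.ids), "sex"] + "_" + meta.loc[list(bc.ids), "diet"])
        res = div.permanova(bc, groups.to_numpy(),
                            n_permutations=cfg.permanova_permutations,
                            seed=_stage_int(cfg.seed, f"prm_{seg}"),
                            grouping_name="sex_diet")
        perma_rows.append({"dataset": f"microbiota_{seg}", "pseudo_f": res.pseudo_f,
                           "r_squared": res.r_squared, "p": res.p_value,
                           "n_permutations": res.n_permutations,
                           "method": res.method})
        pooled.append(prof)

    if alpha_frames:
        write(pd.concat(alpha_frames), out / "diversity" / "alpha.tsv")
        write(pd.concat(fc_frames, ignore_index=True),
              out / "diversity" / "alpha_log2fc.tsv", index=False)
        write(pd.concat(fc_tests, ignore_index=True),
              out / "diversity" / "alpha_diet_tests.tsv", index=False)

    if pooled:
        all_prof = pd.concat(pooled, axis=1)
        bc_all = div.bray_curtis(all_prof)
        write(pd.DataFrame(bc_all.data, index=list(bc_all.ids),
                           columns=list(bc_all.ids)),
              out / "diversity" / "bray_curtis_all.tsv")
        ord_res = div.pcoa(bc_all)
        coords = ord_res.samples.iloc[:, :4]
        coords.index = list(bc_all.ids)
        write(coords, out / "diversity" / "pcoa_coordinates.tsv")
        write(pd.DataFrame({"eigenvalue": ord_res.eigvals,
                            "proportion_explained": ord_res.proportion_explained}),
              out / "diversity" / "pcoa_eigenvalues.tsv")
        seg_labels = meta.loc[list(bc_all.ids), "site"]
        pair_d, comps = div.distance_class_compare(
            bc_all, seg_labels, seed=_stage_int(cfg.seed, "dcls"))
        write(pair_d, out / "diversity" / "segment_pair_distances.tsv", index=False)
        write(comps, out / "diversity" / "segment_pair_comparisons.tsv", index=False)

    for comp, met in data.metabolomes.items():
        dm = div.euclidean_distance(met, scale=cfg.metabolite_scale)
        groups = (meta.loc[list(dm.ids), "sex"] + "_" + meta.loc[list(dm.ids), "diet"])
        res = div.permanova(dm, groups.to_numpy(),
                            n_permutations=cfg.permanova_permutations,
                            seed=_stage_int(cfg.seed, f"prm_{comp}"),
                            grouping_name="sex_diet")
        perma_rows.append({"dataset": f"metabolome_{comp}", "pseudo_f": res.pseudo_f,
                           "r_squared": res.r_squared, "p": res.p_value,
                           "n_permutations": res.n_permutations,
                           "method": res.method})
    write(pd.DataFrame(perma_rows), out / "diversity" / "permanova.tsv", index=False)
    logger.info("diversity: %d datasets tested by PERMANOVA", len(perma_rows))


def _stage_differential(cfg: RunConfig, data: PipelineData, out: Path) -> None:
    write = _writer(cfg)
    meta = _meta_indexed(data)
    profiles = _kept_profiles(data)

    frames = []
    for seg, prof in profiles.items():
        if prof.shape[1] == 0:
            continue
        rec = diff.screen_all_ranks(prof, meta, ranks=cfg.taxon_ranks,
                                    n_perm=cfg.n_perm,
                                    seed=_stage_int(cfg.seed, f"scr_{seg}"),
                                    fdr_scope=cfg.fdr_scope)
        frames.append(rec)
    taxon_screen = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    data.taxon_screen = taxon_screen
    write(taxon_screen, out / "differential" / "taxa.tsv", index=False)

    met_frames = []
    for comp, met in data.metabolomes.items():
        rec = diff.differential_screen(met, meta, n_perm=cfg.n_perm,
                                       seed=_stage_int(cfg.seed, f"scm_{comp}"),
                                       fdr_scope=cfg.fdr_scope)
        met_frames.append(rec)
    met_screen = pd.concat(met_frames, ignore_index=True) if met_frames else pd.DataFrame()
    data.metabolite_screen = met_screen
    write(met_screen, out / "differential" / "metabolites.tsv", index=False)

    for comp, met in data.metabolomes.items():
        sums, tests, fcs = diff.class_aggregate(met, data.class_map, meta)
        write(sums, out / "differential" / f"class_sums_{comp}.tsv")
        write(tests, out / "differential" / f"class_tests_{comp}.tsv", index=False)
        write(fcs, out / "differential" / f"class_log2fc_{comp}.tsv", index=False)

    shifts = []
    for seg, prof in profiles.items():
        if prof.shape[1]:
            shifts.append(diff.presence_shift(prof, meta, site=seg))
    if shifts:
        write(pd.concat(shifts, ignore_index=True),
              out / "differential" / "presence_shifts.tsv", index=False)

    # forest-plot statistics for the most diet-responsive genera
    genus_mats = {seg: diff.aggregate_lineage(prof, "genus")
                  for seg, prof in profiles.items() if prof.shape[1]}
    genus_rec = taxon_screen[taxon_screen["rank"] == "genus"] if len(taxon_screen) else pd.DataFrame()
    forest_rows = []
    if len(genus_rec):
        for sex in SEXES:
            sub = genus_rec[genus_rec["sex"] == sex]
            top = (sub.assign(a=sub["delta"].abs()).groupby("feature_id")["a"].max()
                   .sort_values(ascending=False).head(cfg.n_top_genera))
            for gi, gid in enumerate(top.index):
                agg = diff.bootstrap_segment_aggregate(
                    genus_mats, gid, meta, sex, n_boot=cfg.n_boot,
                    seed=_stage_int(cfg.seed, f"bt_{sex}_{gi}"))
                for seg, eff in agg.segments.items():
                    forest_rows.append({
                        "genus": gid, "sex": sex, "segment": seg,
                        "delta": eff.delta, "boot_sd": eff.boot_sd,
                        "ci_low": eff.ci_low, "ci_high": eff.ci_high,
                        "present": eff.present, "degenerate": eff.degenerate})
    write(pd.DataFrame(forest_rows), out / "differential" / "genus_forest.tsv",
          index=False)
    logger.info("differential: %d taxon records, %d metabolite records, "
                "%d forest rows", len(taxon_screen), len(met_screen),
                len(forest_rows))


def _condition_masks(meta: pd.DataFrame):
    for sex in SEXES:
        for diet in DIETS:
            yield f"{sex}_{diet}", (meta["sex"] == sex) & (meta["diet"] == diet)


def _stage_crossomics(cfg: RunConfig, data: PipelineData, out: Path) -> None:
    write = _writer(cfg)
    meta = _meta_indexed(data)
    profiles = _kept_profiles(data)

    datasets = {}
    for seg, prof in profiles.items():
        if prof.shape[1]:
            datasets[f"microbiota_{seg}"] = xo.pig_matrix(prof, meta)
    for comp, met in data.metabolomes.items():
        datasets[f"metabolome_{comp}"] = xo.pig_matrix(met, meta)

    density_frames = {}
    seed_i = 0
    for cond, mask in _condition_masks(meta):
        cond_pigs = set(meta.loc[mask.to_numpy(), "pig_id"]) if mask.any() else set()
        blocks = []
        names = list(datasets)
        for i, a_name in enumerate(names):
            for b_name in names[i + 1:]:
                a = datasets[a_name]
                b = datasets[b_name]
                a = a.loc[:, [c for c in a.columns if c in cond_pigs]]
                b = b.loc[:, [c for c in b.columns if c in cond_pigs]]
                seed_i += 1
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    blk = xo.correlation_block(
                        a, b, a_name, b_name, condition=cond,
                        n_perm=cfg.n_perm,
                        seed=_stage_int(cfg.seed, f"xo{seed_i}"))
                if blk is not None:
                    blocks.append(blk)
        dens = xo.density_matrix(blocks, alpha=cfg.alpha)
        density_frames[cond] = dens
        write(dens, out / "crossomics" / f"density_{cond}.tsv")
    logger.info("crossomics: density matrices for %d conditions",
                len(density_frames))

    # focused block: diet-responsive taxa x bacterially-linked metabolites
    annotation = example_annotation_map(data.class_map)
    ann_path = out / "crossomics" / "annotation_map.tsv"
    write(annotation.rename("bacterial_link").to_frame().reset_index()
          .rename(columns={"index": "metabolite_id"}), ann_path, index=False)
    if data.taxon_screen is not None and len(data.taxon_screen):
        sp = data.taxon_screen
        sp = sp[(sp["rank"] == "species") & (sp["site"] == "duodenojejunum")
                & (sp["p_perm"] <= cfg.alpha)]
        top_taxa = list(pd.unique(sp["feature_id"]))[:40]
        if top_taxa and "duodenojejunum" in profiles:
            taxa_pig = xo.pig_matrix(profiles["duodenojejunum"].loc[top_taxa], meta)
            for comp, met in data.metabolomes.items():
                keep = xo.annotation_filter(met.index, annotation)
                if not keep:
                    continue
                met_pig = xo.pig_matrix(met.loc[keep], meta)
                blk = xo.correlation_block(
                    taxa_pig, met_pig, "microbiota_duodenojejunum",
                    f"metabolome_{comp}", n_perm=cfg.n_perm,
                    seed=_stage_int(cfg.seed, f"xf_{comp}"))
                if blk is not None:
                    write(blk.tidy(), out / "crossomics" / f"block_dj_{comp}.tsv",
                          index=False)

    # microbe-metabolite-phenotype triads
    if data.phenotypes is not None and "duodenojejunum" in profiles \
            and data.metabolomes:
        pheno = data.phenotypes.set_index("pig_id").drop(columns=["sex", "diet"])
        pheno_pig = pheno.T
        taxa_pig = xo.pig_matrix(profiles["duodenojejunum"], meta)
        comp = list(data.metabolomes)[0]
        met_pig = xo.pig_matrix(data.metabolomes[comp], meta)
        triads = xo.triad_screen(taxa_pig, met_pig, pheno_pig, alpha=cfg.alpha,
                                 taxon_site="duodenojejunum", compartment=comp,
                                 n_perm=cfg.n_perm,
                                 seed=_stage_int(cfg.seed, "tri"))
        write(xo.triad_table(triads), out / "crossomics" / "triads.tsv",
              index=False)
        logger.info("crossomics: %d triads at alpha=%.2f", len(triads), cfg.alpha)


def example_annotation_map(class_map: pd.Series) -> pd.Series:
    """Flag metabolites of classes plausibly linked to bacterial metabolism.

    A stand-in for curated database annotations, synthetic by construction:
    it simply flags whole chemical classes known for microbial involvement
    (bile acids, indoles, amines, amino acids, cresols, alkaloids).
    """
    return class_map.isin(BACTERIAL_CLASSES)
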