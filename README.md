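# gutomics

Segment-stratified statistical analysis of diet effects on the gut
microbiota and metabolome, modelled on a two-diet pig feeding trial: pigs
fed a low-fat (LFD, 3% w/w) or medium-fat (MFD, 12% w/w) diet, with
metagenomic profiles from five gut segments (duodenojejunum, jejunum,
ileum, proximal colon, feces), targeted metabolomics of bile and
duodenojejunal fluid, qPCR bacterial loads and host metabolic phenotypes.
The package is aimed at microbiome researchers who want the full
statistical pipeline of such a study — reusable, seeded and testable —
without the wet-lab or read-level bioinformatics stages: it consumes
profile tables, not FASTQ.

## What it computes

- **Depth QC** — the rarefaction end-slope rule: a sample is kept iff the
  terminal marker-gene discovery rate is ≤ 0.075 marker genes per read
  pair; kept samples are rarefied to their segment's minimum depth
  (multivariate hypergeometric subsampling).
- **Absolute bacterial load** — per-plate standard curve
  Ct = a·log₁₀(copies) + b, inverted and scaled by dilution factor and
  sample mass to 16S copies/g; HOMA-IR = insulin(µU/mL)·glucose(mg/dL)/405.
- **Diversity** — richness S, Shannon H (nats), Gini–Simpson 1−Σp²,
  Pielou J = H/ln S, with per-sex MFD/LFD log₂ fold changes; Bray–Curtis
  and Euclidean distances, classical PCoA, and PERMANOVA
  (pseudo-F = [SS_B/(a−1)]/[SS_W/(N−a)]) with exhaustive label enumeration
  on small designs.
- **Differential testing** — Cliff's delta
  δ = (#{x>y} − #{x<y})/(mn) between diet groups per sex × segment
  stratum, two-sided permutation p-values (n = 2000), Benjamini–Hochberg
  q within stratum, lineage aggregation to all seven ranks,
  presence/absence shift calls, metabolite-class sums with Wilcoxon tests,
  and cross-segment bootstrap variability of genus-level deltas
  (pigs resampled within diet, SD + 95% percentile interval).
- **Cross-omics networks** — Spearman correlation blocks between
  pig-matched layers, proportion-significant density matrices per
  diet × sex condition, bacterial-metabolism annotation filtering, and
  microbe–metabolite–phenotype triads significant on all three edges.
- **Synthetic cohort generator** — a logistic-normal multi-omics cohort
  (2 diets × 2 sexes × 9 pigs, 5 segments, 2 compartments) with planted
  effects whose ground truth drives every verification above.

## Worked example

```python
from gutomics import simulate as sim
from gutomics import differential as diff
from gutomics.preprocess import qc_filter, homa_ir

cohort = sim.simulate_cohort(sim.default_config(seed=42))
meta = cohort.samples.set_index("sample_id")
kept = sum(d.kept for d in qc_filter(cohort.rarefaction_curves))
print(f"samples passing depth QC: {kept}/180")

rec = diff.differential_screen(cohort.taxon_profiles["jejunum"], meta,
                               n_perm=2000, seed=0)
top = rec.reindex(rec.delta.abs().sort_values(ascending=False).index).head(5)
for r in top.itertuples():
    print(r.feature_id.split("|s__")[1], r.sex,
          f"delta={r.delta:+.2f} p={r.p_perm:.4f} q={r.q:.3f}")
print(f"HOMA-IR(4.05, 100) = {homa_ir(4.05, 100.0):.2f}")
```

prints

```
samples passing depth QC: 155/180
Bifidobacterium_sp1 male delta=+0.95 p=0.0010 q=0.150
Streptococcus_sp1 female delta=+0.80 p=0.0025 q=0.375
Lactobacillus_sp1 male delta=-0.80 p=0.0025 q=0.187
Oscillibacter_sp2 male delta=+0.78 p=0.0050 q=0.225
Lactobacillus_sp1 female delta=-0.75 p=0.0070 q=0.475
HOMA-IR(4.05, 100) = 1.00
```

25 of 180 samples were flagged as undersequenced (10% were generated
shallow on purpose).  The five largest jejunal effect sizes are exactly
the effects the default cohort plants there — Bifidobacterium enriched
and Lactobacillus depleted under the medium-fat diet, the Streptococcus
enrichment only in females — with permutation p-values around the 1/2001
resolution floor and BH q-values reflecting the 150-taxon multiplicity.

## Command line

```sh
gutomics all --seed 1 --out run1          # simulate → qc → diversity →
                                          # differential → crossomics
gutomics qc --config run.yaml             # single stage, YAML-configured
```

Every output TSV carries a provenance header (version, seed, config
digest); a rerun with the same seed and configuration is byte-identical.

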