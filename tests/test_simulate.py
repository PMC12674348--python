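"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from gutomics import simulate as sim
from gutomics.config import CohortConfig, ConfigurationError, PlantedEffect
from gutomics.preprocess import end_slope, qc_filter
from gutomics.stats import cliffs_delta, spearman, wilcoxon_rank_sum


def bare_config(seed=0, **kw):
    """No planted effects, no correlated pairs."""
    return CohortConfig(seed=seed, **kw)


class TestCohortDesign:
    def test_design_arithmetic(self):
        cfg = bare_config(n_per_group=9)
        samples, phen = sim.generate_cohort(cfg)
        assert len(phen) == 36
        meta = samples.groupby("layer").size()
        assert meta["metagenome"] == 36 * 5
        assert meta["metabolome"] == 36 * 2
        # diet and sex constant per pig, (pig, site) unique
        per_pig = samples.groupby("pig_id")[["sex", "diet"]].nunique()
        assert (per_pig == 1).all().all()
        assert not samples.duplicated(["pig_id", "site"]).any()

    def test_determinism(self):
        cfg = sim.default_config(seed=5, n_per_group=3, n_taxa=30, n_metabolites=24)
        a = sim.simulate_cohort(cfg)
        b = sim.simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        for seg in cfg.segments:
            pd.testing.assert_frame_equal(a.taxon_profiles[seg], b.taxon_profiles[seg])
        pd.testing.assert_frame_equal(a.qpcr_ct, b.qpcr_ct)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigurationError, match="n_per_group"):
            bare_config(n_per_group=2)
        with pytest.raises(ConfigurationError, match="n_taxa"):
            bare_config(n_taxa=0)
        with pytest.raises(ConfigurationError, match="effect_size"):
            PlantedEffect("x", "taxon", ((None, "jejunum"),), 1.5)

    def test_phenotype_shift_recovery(self):
        """HDL x1.3 in MFD: the mean group ratio converges to 1.3."""
        ratios = []
        for seed in range(200):
            cfg = bare_config(seed=seed, effect_table=(
                PlantedEffect("hdl_cholesterol", "phenotype", ((None, None),),
                              1.3, mode="multiplier"),))
            _, phen = sim.generate_cohort(cfg)
            ratios.append(phen[phen.diet == "MFD"].hdl_cholesterol.mean()
                          / phen[phen.diet == "LFD"].hdl_cholesterol.mean())
        ratios = np.array(ratios)
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 1.3) < 3 * se + 0.01


class TestTaxonProfiles:
    def test_compositional_closure(self, cohort):
        for seg, prof in cohort.taxon_profiles.items():
            sums = prof.sum(axis=0)
            assert np.allclose(sums, 100.0, atol=1e-6)
            assert (prof.to_numpy() >= 0).all()

    def test_unknown_feature_rejected(self):
        cfg = bare_config(effect_table=(
            PlantedEffect("k__Nope|p__X|c__X|o__X|f__X|g__X|s__X_sp1", "taxon",
                          ((None, "jejunum"),), 0.5),))
        samples, _ = sim.generate_cohort(cfg)
        with pytest.raises(ConfigurationError, match="unknown taxon"):
            sim.generate_taxon_profiles(samples, cfg)

    def test_planted_delta_realised_in_expectation(self):
        """Planted delta 0.8 in female jejunum: mean empirical delta within 0.1."""
        target = sim.species_lineage("Streptococcus", 60)
        deltas = []
        for seed in range(200):
            cfg = bare_config(seed=seed, n_taxa=60, effect_table=(
                PlantedEffect(target, "taxon", (("female", "jejunum"),), 0.8),))
            samples, _ = sim.generate_cohort(cfg)
            profiles, truth = sim.generate_taxon_profiles(samples, cfg)
            meta = samples.set_index("sample_id")
            prof = profiles["jejunum"]
            m = meta.loc[prof.columns]
            female = m.sex == "female"
            vals = prof.loc[target].to_numpy()
            x = vals[(female & (m.diet == "MFD")).to_numpy()]
            y = vals[(female & (m.diet == "LFD")).to_numpy()]
            deltas.append(cliffs_delta(x, y))
        assert abs(np.mean(deltas) - 0.8) < 0.1
        # truth table records the planted stratum exactly once
        row = truth[(truth.feature_id == target) & (truth.sex == "female")
                    & (truth.site == "jejunum")]
        assert len(row) == 1 and row.true_effect.iloc[0] == 0.8

    def test_truth_table_covers_every_feature_stratum(self, cohort, small_config):
        t = cohort.taxon_truth
        expected = small_config.n_taxa * 2 * len(small_config.segments)
        assert len(t) == expected
        assert not t.duplicated(["feature_id", "sex", "site"]).any()

    def test_proximal_distal_gradient(self, cohort):
        bacteroidota = [l for l in cohort.taxon_profiles["jejunum"].index
                        if "p__Bacteroidota" in l]
        prox = cohort.taxon_profiles["jejunum"].loc[bacteroidota].to_numpy().sum(axis=0).mean()
        dist = cohort.taxon_profiles["feces"].loc[bacteroidota].to_numpy().sum(axis=0).mean()
        assert dist > 10 * max(prox, 1e-9)


class TestMetabolomes:
    def test_nonnegative_and_classed(self, cohort, small_config):
        for comp, m in cohort.metabolomes.items():
            assert (m.to_numpy() > 0).all()
        assert set(cohort.class_map["class"]).issubset(set(sim.METABOLITE_CLASSES))

    def test_unknown_class_rejected(self):
        cfg = bare_config(effect_table=(
            PlantedEffect("class:unobtainium", "metabolite", ((None, "bile"),),
                          2.0, mode="multiplier"),))
        samples, _ = sim.generate_cohort(cfg)
        with pytest.raises(ConfigurationError, match="unknown metabolite class"):
            sim.generate_metabolomes(samples, cfg)

    def test_planted_spearman_recovered(self):
        """rho=0.7 taxon-metabolite pair: mean estimate within 0.1 at n=18."""
        rhos = []
        for seed in range(60):
            cfg = sim.default_config(seed=seed)
            samples, _ = sim.generate_cohort(cfg)
            mets, _, _ = sim.generate_metabolomes(samples, cfg)
            profiles, _ = sim.generate_taxon_profiles(samples, cfg)
            meta = samples.set_index("sample_id")
            pair = cfg.correlated_pairs[0]
            tax = profiles[pair.taxon_site].loc[pair.taxon_id]
            met = mets[pair.compartment].loc[pair.metabolite_id]
            tv = pd.Series(tax.to_numpy(), index=meta.loc[tax.index, "pig_id"])
            mv = pd.Series(met.to_numpy(), index=meta.loc[met.index, "pig_id"])
            # one sex = 18 pigs, matching the planted-recovery design
            pigs = [p for p in mv.index if p.startswith("F")]
            rho, _, _ = spearman(tv[pigs].to_numpy(), mv[pigs].to_numpy())
            rhos.append(rho)
        assert abs(np.nanmean(rhos) - 0.7) < 0.1

    def test_class_shift_power(self):
        """TG x2 in MFD reaches Wilcoxon p<=0.05 in >=80% of cohorts."""
        hits = 0
        reps = 150
        for seed in range(reps):
            cfg = bare_config(seed=seed, effect_table=(
                PlantedEffect("class:triacylglycerols", "metabolite",
                              ((None, "dj_fluid"),), 2.0, mode="multiplier"),))
            samples, _ = sim.generate_cohort(cfg)
            mets, _, cat = sim.generate_metabolomes(samples, cfg)
            meta = samples.set_index("sample_id")
            m = mets["dj_fluid"]
            tg = cat.index[cat["class"] == "triacylglycerols"]
            sums = m.loc[tg].sum(axis=0)
            md = meta.loc[sums.index]
            sel = md.sex == "female"
            p = wilcoxon_rank_sum(
                sums[(sel & (md.diet == "MFD")).to_numpy()].to_numpy(),
                sums[(sel & (md.diet == "LFD")).to_numpy()].to_numpy())
            hits += p <= 0.05
        assert hits / reps >= 0.8


class TestRarefactionCurves:
    def test_monotone_and_slope_separation(self, cohort, small_config):
        cfg = small_config
        for c in cohort.rarefaction_curves:
            assert np.all(np.diff(c.markers) >= 0)
            s = end_slope(c)
            # closed-form generating slope: (pool/d0) * exp(-depth/d0)
            gen = (cfg.marker_pool / cfg.discovery_scale
                   * np.exp(-c.final_depth / cfg.discovery_scale))
            assert s == pytest.approx(gen, rel=0.15)
            if c.final_depth >= cfg.depth_range[0]:
                assert s < 0.075
            else:
                assert s > 0.075

    def test_unsaturated_fraction_within_binomial_band(self):
        cfg = bare_config(seed=42, n_per_group=5, unsaturated_fraction=0.2)
        samples, _ = sim.generate_cohort(cfg)
        curves = sim.generate_rarefaction_curves(samples, cfg)
        assert len(curves) == 100
        flagged = sum(not d.kept for d in qc_filter(curves))
        # binomial 95% band around 20 of 100
        sd = np.sqrt(100 * 0.2 * 0.8)
        assert abs(flagged - 20) <= 1.96 * sd

    def test_invalid_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            bare_config(n_curve_points=0)


class TestQpcr:
    def test_noise_free_exact_inversion(self):
        from gutomics.preprocess import fit_standard_curve, qpcr_load
        cfg = bare_config(seed=1, n_per_group=3, qpcr_ct_noise=0.0)
        samples, _ = sim.generate_cohort(cfg)
        ct, std, truth = sim.generate_qpcr(samples, cfg)
        curve = fit_standard_curve(std.log10_copies, std.ct)
        for _, row in ct.iterrows():
            res = qpcr_load(row.ct, curve, row.dilution_factor, row.mass_mg,
                            sample_id=row.sample_id)
            expected = truth.set_index("sample_id").loc[row.sample_id,
                                                        "copies_per_gram"]
            assert abs(res.copies_per_gram - expected) / expected < 1e-9

    def test_gradient_monotone_in_medians(self, cohort, small_config):
        truth = cohort.load_truth
        medians = [truth[truth.site == seg].copies_per_gram.median()
                   for seg in small_config.segments]
        assert all(a < b for a, b in zip(medians, medians[1:]))

    def test_planted_load_depletion_power(self):
        """Female jejunal load x0.3 in MFD: Wilcoxon p<=0.05 in >=80% of reps."""
        hits = 0
        reps = 150
        for seed in range(reps):
            cfg = bare_config(seed=seed, effect_table=(
                PlantedEffect("jejunum", "load", (("female", "jejunum"),),
                              0.3, mode="multiplier"),))
            samples, _ = sim.generate_cohort(cfg)
            _, _, truth = sim.generate_qpcr(samples, cfg)
            t = truth[(truth.site == "jejunum") & (truth.sex == "female")]
            p = wilcoxon_rank_sum(
                t[t.diet == "MFD"].copies_per_gram.to_numpy(),
                t[t.diet == "LFD"].copies_per_gram.to_numpy())
            hits += p <= 0.05
        assert hits / reps >= 0.8

    def test_unknown_segment_effect_rejected(self):
        cfg = bare_config(effect_table=(
            PlantedEffect("stomach", "load", ((None, "stomach"),), 0.5,
                          mode="multiplier"),))
        samples, _ = sim.generate_cohort(cfg)
        with pytest.raises(ConfigurationError, match="unknown segment"):
            sim.generate_qpcr(samples, cfg)
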