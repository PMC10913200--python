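"""Generator contracts: planted truth, determinism, count moments."""

import numpy as np
import pandas as pd
import pytest

from triadex import synthetic_data as sd, triad_classify as tc
from triadex.synthetic_data import ConfigError, SimulationConfig


class TestConfigValidation:
    def test_proportions_must_sum_to_one(self):
        cfg = SimulationConfig(class_proportions={13: 0.9})
        with pytest.raises(ConfigError, match="sum"):
            cfg.validate()

    def test_effect_below_threshold_infeasible(self):
        cfg = SimulationConfig(effect_size=0.5, class_proportions={4: 0.5, 13: 0.5})
        with pytest.raises(ConfigError, match="effect_size"):
            cfg.validate()

    def test_effect_below_threshold_fine_when_all_conserved(self):
        SimulationConfig(
            effect_size=0.5, class_proportions={13: 1.0}, dig_proportion=0.0
        ).validate()

    def test_coupling_magnitude_bounded(self):
        cfg = SimulationConfig(couplings={("body", "CCGG"): 1.0})
        with pytest.raises(ConfigError, match="coupling"):
            cfg.validate()

    def test_nonpositive_parent_trait_mean_rejected(self):
        cfg = SimulationConfig()
        cfg.parent_trait_means["P1"]["fresh_weight"] = 0.0
        with pytest.raises(ConfigError, match="positive"):
            cfg.validate()


class TestExpressionGeneration:
    def test_determinism_same_seed(self):
        cfg = SimulationConfig(n_genes=150, seed=1)
        m1, _, t1 = sd.generate_triad_dataset(cfg)
        m2, _, t2 = sd.generate_triad_dataset(SimulationConfig(n_genes=150, seed=1))
        assert m1.fpkm.to_csv() == m2.fpkm.to_csv()
        assert m1.counts.to_csv() == m2.counts.to_csv()
        assert t1.class_table.to_csv() == t2.class_table.to_csv()

    def test_conserved_gene_has_equal_means(self, small_sim):
        _, _, _, truth = small_sim
        conserved = (
            truth.class_table.groupby("gene_id")["subcategory"]
            .apply(lambda s: (s == 13).all())
        )
        genes = conserved.index[conserved]
        assert len(genes) > 0
        means = truth.mean_fpkm.loc[genes]
        assert (means.nunique(axis=1) == 1).all()

    def test_high_parent_dominance_realizes_stated_means(self):
        """A biased-parent gene (F1 = high parent A) plants
        mean(F1) = mean(A) and (A + pc) = 2^effect * (B + pc)."""
        cfg = SimulationConfig(
            n_genes=60, seed=3, effect_size=2.0,
            class_proportions={4: 1.0}, dig_proportion=0.0,
        )
        _, design, truth = sd.generate_triad_dataset(cfg)
        m = truth.mean_fpkm
        np.testing.assert_allclose(m["F12"], m["P1"])
        np.testing.assert_allclose((m["P1"] + 1) / (m["P2"] + 1), 4.0)

    def test_noise_free_consistency(self, small_sim):
        _, _, design, truth = small_sim
        for hybrid in design.hybrids:
            pa, pb = design.triad_parents(hybrid)
            got = tc.classify_from_means(truth.mean_fpkm, pa, pb, hybrid)
            planted = truth.class_table.query("hybrid == @hybrid")
            assert (
                got.set_index("gene_id")["subcategory"]
                == planted.set_index("gene_id")["subcategory"]
            ).all()

    def test_count_moments_match_config(self):
        """Empirical NB mean and dispersion agree with the config at
        5000 genes (Monte-Carlo tolerance)."""
        cfg = SimulationConfig(
            n_genes=5000, seed=9, class_proportions={13: 1.0}, dig_proportion=0.0
        )
        matrix, design, truth = sd.generate_triad_dataset(cfg)
        counts = matrix.counts[design.samples_of("P1")].to_numpy(dtype=float)
        mu = (
            truth.mean_fpkm["P1"].to_numpy()
            * truth.gene_lengths.to_numpy() / 1000.0
            * cfg.library_scale
        )
        big = mu > 500
        rel_err = np.abs(counts.mean(axis=1)[big] - mu[big]) / mu[big]
        assert np.median(rel_err) < 0.2
        # pooled dispersion: var = mu + disp * mu^2 -> disp estimate
        v = counts.var(axis=1, ddof=1)[big]
        disp_hat = np.median((v - mu[big]) / mu[big] ** 2)
        assert disp_hat == pytest.approx(cfg.dispersion, rel=0.5)

    def test_dig_truth_is_reciprocally_divergent(self, small_sim):
        _, _, design, truth = small_sim
        digs = truth.dig_table.query("combination == 'P1xP2'")
        assert len(digs) > 0
        wide = digs.pivot(index="gene_id", columns="hybrid", values="origin")
        assert (wide["F12"] != wide["F21"]).all()


class TestMethylationGeneration:
    def test_coupling_signs_realized(self):
        cfg = SimulationConfig(n_genes=800, seed=13)
        _, design, truth = sd.generate_triad_dataset(cfg)
        models = sd.generate_gene_models(truth.gene_lengths, seed=cfg.seed)
        sites, truth_m = sd.generate_methylation(cfg, models, truth)
        from triadex import methylation_link as ml

        assignments = ml.assign_regions(sites, models)
        levels = ml.region_level(sites, assignments)
        corr = ml.meth_expr_correlation(levels, truth.mean_fpkm)
        merged = corr.merge(truth_m.expected_sign, on=["region", "context"])
        assert (np.sign(merged["r"]) == merged["sign"]).all()

    def test_body_ccgg_correlation_near_coupling(self):
        """With coupling +0.5 the realized Pearson r lands in [0.4, 0.6]
        (the coupling is linear-in-expression by construction)."""
        cfg = SimulationConfig(n_genes=2000, seed=17)
        _, design, truth = sd.generate_triad_dataset(cfg)
        models = sd.generate_gene_models(truth.gene_lengths, seed=cfg.seed)
        sites, _ = sd.generate_methylation(cfg, models, truth)
        from triadex import methylation_link as ml

        assignments = ml.assign_regions(sites, models)
        levels = ml.region_level(sites, assignments)
        corr = ml.meth_expr_correlation(levels, truth.mean_fpkm).set_index(
            ["region", "context"]
        )
        assert 0.4 <= corr.loc[("body", "CCGG"), "r"] <= 0.6

    def test_zero_sites_requested_gives_empty_table(self):
        cfg = SimulationConfig(
            n_genes=20, seed=1, sites_per_region=0.0, intergenic_site_rate=0.0
        )
        _, _, truth = sd.generate_triad_dataset(cfg)
        models = sd.generate_gene_models(truth.gene_lengths, seed=1)
        sites, truth_m = sd.generate_methylation(cfg, models, truth)
        assert len(sites.sites) == 0
        assert len(truth_m.assignments) == 0


class TestPhenotypeGeneration:
    def test_planted_mph_realized_exactly_without_noise(self):
        cfg = SimulationConfig(phenotype_cv=0.0)
        design = sd.generate_design(cfg)
        pheno, truth = sd.generate_phenotypes(cfg, design)
        from triadex import heterosis_metrics as hm

        het = hm.heterosis_indices(pheno, design).set_index(["hybrid", "trait"])
        for _, row in truth.heterosis.iterrows():
            got = het.loc[(row["hybrid"], row["trait"])]
            assert got["mph"] == pytest.approx(row["mph"], abs=1e-9)
            assert got["bph"] == pytest.approx(row["bph"], abs=1e-9)

    def test_hybrid_mean_formula(self):
        """Planted MPH of 30% on parent means 10 and 20 puts the hybrid
        population mean at 19.5 (= 15 x 1.3)."""
        cfg = SimulationConfig(
            parents=("P1", "P2"),
            parentage={"F12": ("P1", "P2"), "F21": ("P2", "P1")},
            traits=("mass",),
            parent_trait_means={"P1": {"mass": 10.0}, "P2": {"mass": 20.0}},
            phenotype_mph={"F12": {"mass": 30.0}, "F21": {"mass": 0.0}},
            phenotype_cv=0.0,
        )
        design = sd.generate_design(cfg)
        pheno, truth = sd.generate_phenotypes(cfg, design)
        means = pheno.groupby("genotype")["value"].mean()
        assert means["F12"] == pytest.approx(19.5)
        assert means["F21"] == pytest.approx(15.0)  # MPH 0 -> mid-parent
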