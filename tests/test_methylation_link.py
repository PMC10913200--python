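"""Region assignment, level aggregation, correlation, DMS concordance."""

import numpy as np
import pandas as pd
import pytest

from triadex import methylation_link as ml, triad_classify as tc
from triadex.io_formats import MethylationSiteTable


def site_table(rows, genotypes=("P1", "P2", "F12")):
    df = pd.DataFrame(rows)
    for g in genotypes:
        df[g] = df.get(g, 1.0)
    df.insert(
        0, "site_id",
        df["chrom"] + ":" + df["pos"].astype(str) + ":" + df["context"],
    )
    return MethylationSiteTable(sites=df, genotypes=tuple(genotypes))


def gene(gene_id="g1", chrom="Chr01", start=10000, end=12000, strand="+"):
    return {
        "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
        "strand": strand,
    }


class TestAssignRegions:
    def _sites(self):
        return site_table(
            [
                {"chrom": "Chr01", "pos": 9500, "context": "CCGG"},
                {"chrom": "Chr01", "pos": 10500, "context": "CCGG"},
                {"chrom": "Chr01", "pos": 13000, "context": "CCWGG"},
                {"chrom": "Chr01", "pos": 50000, "context": "CCGG"},
            ]
        )

    def test_plus_strand(self):
        out = ml.assign_regions(self._sites(), pd.DataFrame([gene()]))
        regions = out.set_index("site_id")["region"]
        assert regions["Chr01:9500:CCGG"] == "upstream2k"
        assert regions["Chr01:10500:CCGG"] == "body"
        assert regions["Chr01:13000:CCWGG"] == "downstream2k"
        assert regions["Chr01:50000:CCGG"] == "intergenic"

    def test_strand_flip_swaps_flanks_fixes_body(self):
        plus = ml.assign_regions(self._sites(), pd.DataFrame([gene(strand="+")]))
        minus = ml.assign_regions(self._sites(), pd.DataFrame([gene(strand="-")]))
        swap = {"upstream2k": "downstream2k", "downstream2k": "upstream2k",
                "body": "body", "intergenic": "intergenic"}
        merged = plus.merge(minus, on="site_id", suffixes=("_plus", "_minus"))
        assert (merged["region_minus"] == merged["region_plus"].map(swap)).all()

    def test_window_clipped_at_chromosome_start(self):
        sites = site_table([{"chrom": "Chr01", "pos": 1, "context": "CCGG"}])
        out = ml.assign_regions(sites, pd.DataFrame([gene(start=100, end=500)]))
        assert out["region"].iloc[0] == "upstream2k"

    def test_site_may_hit_multiple_genes(self):
        genes = pd.DataFrame(
            [gene("g1", start=10000, end=12000), gene("g2", start=12500, end=14000)]
        )
        sites = site_table([{"chrom": "Chr01", "pos": 12200, "context": "CCGG"}])
        out = ml.assign_regions(sites, genes)
        assert set(zip(out["gene_id"], out["region"])) == {
            ("g1", "downstream2k"), ("g2", "upstream2k")
        }


class TestRegionLevel:
    def test_sum_and_context_additivity(self):
        sites = site_table(
            [
                {"chrom": "Chr01", "pos": 10500, "context": "CCGG",
                 "P1": 2.0, "P2": 1.0, "F12": 0.5},
                {"chrom": "Chr01", "pos": 11000, "context": "CCGG",
                 "P1": 3.0, "P2": 1.0, "F12": 0.5},
                {"chrom": "Chr01", "pos": 11500, "context": "CCWGG",
                 "P1": 1.0, "P2": 4.0, "F12": 0.5},
            ]
        )
        assignments = ml.assign_regions(sites, pd.DataFrame([gene()]))
        levels = ml.region_level(sites, assignments).set_index(
            ["gene_id", "region", "context"]
        )
        assert levels.loc[("g1", "body", "CCGG"), "P1"] == 5.0
        assert levels.loc[("g1", "body", "all"), "P1"] == 6.0  # 5 + 1
        assert levels.loc[("g1", "body", "all"), "P2"] == 6.0  # 2 + 4
        # empty region reported as zero
        assert levels.loc[("g1", "upstream2k", "CCGG"), "P1"] == 0.0

    def test_all_context_additivity_everywhere(self, small_sim):
        from triadex import synthetic_data as sd

        cfg, _, design, truth = small_sim
        models = sd.generate_gene_models(truth.gene_lengths, seed=cfg.seed)
        sites, _ = sd.generate_methylation(cfg, models, truth)
        assignments = ml.assign_regions(sites, models)
        levels = ml.region_level(sites, assignments)
        wide = levels.pivot_table(
            index=["gene_id", "region"], columns="context",
            values=list(sites.genotypes), aggfunc="first",
        )
        for g in sites.genotypes:
            np.testing.assert_allclose(
                wide[(g, "all")], wide[(g, "CCGG")] + wide[(g, "CCWGG")], atol=1e-9
            )


class TestCorrelation:
    def _levels(self, values, genotypes=("P1", "P2")):
        rows = []
        for i, v in enumerate(values):
            row = {"gene_id": f"g{i}", "region": "body", "context": "CCGG"}
            for g in genotypes:
                row[g] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def test_perfect_linear_relations(self):
        expr = pd.DataFrame(
            {"P1": [1.0, 2.0, 3.0, 4.0], "P2": [1.0, 2.0, 3.0, 4.0]},
            index=[f"g{i}" for i in range(4)],
        )
        up = ml.meth_expr_correlation(self._levels([2.0, 4.0, 6.0, 8.0]), expr)
        assert up["r"].iloc[0] == pytest.approx(1.0)
        down = ml.meth_expr_correlation(self._levels([99.0, 98.0, 97.0, 96.0]), expr)
        assert down["r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        expr = pd.DataFrame(
            {"P1": [1.0, 2.0, 3.0], "P2": [1.0, 2.0, 3.0]},
            index=["g0", "g1", "g2"],
        )
        out = ml.meth_expr_correlation(self._levels([5.0, 5.0, 5.0]), expr)
        assert np.isnan(out["r"].iloc[0])


class TestClassifyDms:
    def test_shares_the_expression_mapping(self):
        """Threshold classification of site RPM reproduces the 27-pattern
        table exactly (same code path as expression)."""
        e = 2.0
        offsets = {  # (B, F) offsets on the log2(rpm+1) scale, A at base
            1: (0, e), 4: (-e, 0), 11: (-2 * e, -e), 13: (0, 0),
        }
        base = 6.0
        rows = []
        for sub, (db, df_) in offsets.items():
            rows.append(
                {
                    "site_id": f"s{sub}",
                    "P1": 2.0 ** base - 1,
                    "P2": 2.0 ** (base + db) - 1,
                    "F12": 2.0 ** (base + df_) - 1,
                }
            )
        rpm = pd.DataFrame(rows).set_index("site_id")
        out = ml.classify_dms(
            site_rpm=rpm, parent_a="P1", parent_b="P2", hybrid="F12"
        ).set_index("site_id")
        for sub in offsets:
            assert out.loc[f"s{sub}", "subcategory"] == sub
        assert out.loc["s1", "major"] == "OMS"
        assert out.loc["s4", "major"] == "BMS"
        assert out.loc["s11", "major"] == "AMS"
        assert out.loc["s13", "major"] == "conserved"

    def test_call_mode_matches_rpm_mode(self):
        from triadex import de_core

        rng = np.random.default_rng(6)
        rpm = pd.DataFrame(
            rng.gamma(2, 5, size=(40, 3)), columns=["P1", "P2", "F12"],
            index=[f"s{i}" for i in range(40)],
        )
        via_rpm = ml.classify_dms(
            site_rpm=rpm, parent_a="P1", parent_b="P2", hybrid="F12"
        )
        calls = {
            "pp": de_core.calls_from_means(rpm["P1"], rpm["P2"], "P1", "P2"),
            "fa": de_core.calls_from_means(rpm["F12"], rpm["P1"], "F12", "P1"),
            "fb": de_core.calls_from_means(rpm["F12"], rpm["P2"], "F12", "P2"),
        }
        via_calls = ml.classify_dms(calls["pp"], calls["fa"], calls["fb"])
        assert (
            via_rpm["subcategory"].to_numpy() == via_calls["subcategory"].to_numpy()
        ).all()

    def test_missing_call_rejected(self):
        from triadex.io_formats import ValidationError

        with pytest.raises(ValidationError):
            ml.classify_dms(calls_pp=pd.DataFrame(), calls_fa=None, calls_fb=None)


class TestMatchRemodeling:
    def _inputs(self, meth_sub, expr_sub):
        expr = pd.DataFrame(
            {"gene_id": ["g1"], "hybrid": ["F12"], "subcategory": [expr_sub]}
        )
        dms = pd.DataFrame(
            {"site_id": ["s1"], "hybrid": ["F12"], "subcategory": [meth_sub]}
        )
        assignments = pd.DataFrame(
            {
                "site_id": ["s1"], "context": ["CCGG"],
                "gene_id": ["g1"], "region": ["body"],
            }
        )
        return expr, dms, assignments

    @pytest.mark.parametrize(
        "meth_sub,expr_sub,label",
        [
            (2, 7, "conflicting"),  # F1>PA>PB methylation vs PB>PA>F1 expression
            (4, 4, "consistent"),
            (13, 4, "unmatched"),
        ],
    )
    def test_labels(self, meth_sub, expr_sub, label):
        out = ml.match_remodeling(*self._inputs(meth_sub, expr_sub))
        assert out["label"].iloc[0] == label

    def test_multi_site_gene_carries_both_flags(self):
        expr = pd.DataFrame(
            {"gene_id": ["g1"], "hybrid": ["F12"], "subcategory": [4]}
        )
        dms = pd.DataFrame(
            {
                "site_id": ["s1", "s2"], "hybrid": ["F12", "F12"],
                "subcategory": [4, 9],
            }
        )
        assignments = pd.DataFrame(
            {
                "site_id": ["s1", "s2"], "context": ["CCGG", "CCGG"],
                "gene_id": ["g1", "g1"], "region": ["body", "body"],
            }
        )
        out = ml.match_remodeling(expr, dms, assignments)
        assert out["label"].iloc[0] == "both"
        assert out["consistent"].iloc[0] and out["conflicting"].iloc[0]


class TestFeatureDistribution:
    def test_fractions(self):
        dms = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3"],
                "hybrid": ["F12"] * 3,
                "subcategory": [4, 2, 13],
            }
        )
        assignments = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s3"],
                "context": ["CCGG"] * 3,
                "gene_id": ["g1", "g2", ""],
                "region": ["body", "upstream2k", "intergenic"],
            }
        )
        out = ml.feature_distribution(dms, assignments).set_index("class_group")
        assert out.loc["NMS", "gene_region_fraction"] == 1.0
        assert out.loc["conserved", "gene_region_fraction"] == 0.0
        assert np.isnan(out.loc["AMS", "gene_region_fraction"])
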