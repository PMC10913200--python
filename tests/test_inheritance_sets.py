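"""DEG set ledger: copDEGs, HEGs, H&P, DIGs, overlaps, maternal origins."""

import numpy as np
import pandas as pd
import pytest

from triadex import de_core, inheritance_sets as isets, synthetic_data as sd
from triadex.inheritance_sets import GeneSetLedger
from triadex.io_formats import TriadDesign, ValidationError

GENES = ["g1", "g2", "g3", "g4"]


def calls_from_directions(a, b, directions):
    return pd.DataFrame(
        {
            "gene_id": GENES,
            "group_a": a,
            "group_b": b,
            "log2fc": [
                {"up": 2.0, "down": -2.0, "ns": 0.0}[d] for d in directions
            ],
            "p_value": [0.001 if d != "ns" else 0.8 for d in directions],
            "direction": directions,
        }
    )


@pytest.fixture
def toy_calls(triad_design):
    # g1: F12 up vs both parents (copDEG up); g2: DE only vs P1;
    # g3: DIG gene (F12 matches P1, F21 matches P2, hybrids differ);
    # g4: nothing anywhere
    return {
        ("P1", "P2"): calls_from_directions("P1", "P2", ["ns", "ns", "up", "ns"]),
        ("F12", "P1"): calls_from_directions("F12", "P1", ["up", "up", "ns", "ns"]),
        ("F12", "P2"): calls_from_directions("F12", "P2", ["up", "ns", "up", "ns"]),
        ("F21", "P1"): calls_from_directions("F21", "P1", ["ns", "ns", "down", "ns"]),
        ("F21", "P2"): calls_from_directions("F21", "P2", ["ns", "ns", "ns", "ns"]),
        ("F12", "F21"): calls_from_directions("F12", "F21", ["up", "ns", "up", "ns"]),
    }


class TestLedger:
    def test_copdeg_rules(self, toy_calls, triad_design):
        ledger = isets.build_deg_ledger(toy_calls, triad_design)
        assert ledger.sets["copDEGs_F12"] == {"g1"}
        assert ledger.directions["copDEGs_F12"]["g1"] == "up"
        # DE vs only one parent is not a copDEG
        assert "g2" not in ledger.sets["copDEGs_F12"]

    def test_hegs_and_hp(self, toy_calls, triad_design):
        ledger = isets.build_deg_ledger(toy_calls, triad_design)
        assert ledger.sets["HEGs_F12_F21"] == {"g1", "g3"}
        assert ledger.sets["PEGs_P1xP2"] == {"g3"}
        assert ledger.sets["HP_F12_F21"] == {"g3"}

    def test_hp_is_exact_intersection_on_toy_sets(self):
        ledger = GeneSetLedger()
        ledger.add("HEGs", {"g1", "g2"}, "toy")
        ledger.add("PEGs", {"g2", "g3"}, "toy")
        assert ledger.sets["HEGs"] & ledger.sets["PEGs"] == {"g2"}

    def test_missing_comparison_named(self, toy_calls, triad_design):
        del toy_calls[("P1", "P2")]
        with pytest.raises(ValidationError, match="P1 vs P2"):
            isets.build_deg_ledger(toy_calls, triad_design)

    def test_reverse_call_lookup_flips_direction(self, toy_calls):
        rev = isets.get_calls(toy_calls, "P2", "P1")
        assert list(rev["direction"]) == ["ns", "ns", "down", "ns"]
        assert rev["log2fc"].iloc[2] == -2.0


class TestDigs:
    def test_forced_example(self, toy_calls, triad_design):
        digs = isets.detect_digs(toy_calls, triad_design, "F12", "F21")
        assert list(digs["gene_id"]) == ["g3"]
        assert digs["origin_F12"].iloc[0] == "P1"
        assert digs["origin_F21"].iloc[0] == "P2"

    def test_not_de_between_hybrids_excluded(self, toy_calls, triad_design):
        toy_calls[("F12", "F21")] = calls_from_directions(
            "F12", "F21", ["up", "ns", "ns", "ns"]
        )
        digs = isets.detect_digs(toy_calls, triad_design, "F12", "F21")
        assert "g3" not in set(digs["gene_id"])

    def test_same_matched_parent_excluded(self, toy_calls, triad_design):
        # make F21 also match P1 (ns vs P1, DE vs P2)
        toy_calls[("F21", "P1")] = calls_from_directions(
            "F21", "P1", ["ns", "ns", "ns", "ns"]
        )
        toy_calls[("F21", "P2")] = calls_from_directions(
            "F21", "P2", ["ns", "ns", "up", "ns"]
        )
        digs = isets.detect_digs(toy_calls, triad_design, "F12", "F21")
        assert len(digs) == 0


class TestOverlap:
    def test_fraction_values(self):
        ledger = GeneSetLedger()
        ledger.add("A", {"g1", "g2", "g3", "g4"}, "toy")
        ledger.add("B", {"g1", "g2"}, "toy")
        ledger.add("C", {"x"}, "toy")
        assert isets.overlap_fraction(ledger, "A", "B") == 50.00
        assert isets.overlap_fraction(ledger, "B", "A") == 100.00
        assert isets.overlap_fraction(ledger, "A", "C") == 0.00

    def test_empty_denominator_flagged(self):
        ledger = GeneSetLedger()
        ledger.add("A", set(), "toy")
        ledger.add("B", {"g1"}, "toy")
        with pytest.raises(ValidationError, match="empty"):
            isets.overlap_fraction(ledger, "A", "B")


class TestMaternalAttribution:
    def test_fraction(self, triad_design):
        digs = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "origin_F12": ["P1", "P1", "P1", "P2"],
                "origin_F21": ["P2", "P2", "P1", "P1"],
            }
        )
        out = isets.maternal_attribution(digs, triad_design).set_index("hybrid")
        assert out.loc["F12", "maternal_fraction"] == 0.75  # maternal P1
        assert out.loc["F21", "maternal_fraction"] == 0.5   # maternal P2
        assert out.loc["combined", "maternal_fraction"] == pytest.approx(0.625)

    def test_no_digs_flagged_undefined(self, triad_design):
        digs = pd.DataFrame({"gene_id": [], "origin_F12": [], "origin_F21": []})
        out = isets.maternal_attribution(digs, triad_design)
        assert out["maternal_fraction"].isna().all()

    def test_missing_origin_rejected(self, triad_design):
        digs = pd.DataFrame(
            {"gene_id": ["g1"], "origin_F12": [""], "origin_F21": ["P2"]}
        )
        with pytest.raises(ValidationError, match="origin"):
            isets.maternal_attribution(digs, triad_design)


@pytest.fixture(scope="module")
def noise_free():
    """Threshold-only calls on the planted mean matrix (no noise)."""
    cfg = sd.SimulationConfig(n_genes=800, seed=23)
    _, design, truth = sd.generate_triad_dataset(cfg)
    means = truth.mean_fpkm
    calls = {}
    pairs = set()
    for name, hybrids in design.combinations.items():
        pa, pb = design.combination_parents(name)
        pairs.add((pa, pb))
        for h in hybrids:
            pairs.update([(h, pa), (h, pb)])
    hyb = design.hybrids
    for i, h1 in enumerate(hyb):
        for h2 in hyb[i + 1:]:
            pairs.add((h1, h2))
    for a, b in sorted(pairs):
        calls[(a, b)] = de_core.calls_from_means(means[a], means[b], a, b)
    return design, truth, calls


class TestSyntheticInvariants:
    """Noise-free set identities on generated data with planted DIGs."""

    def test_planted_digs_recovered_exactly(self, noise_free):
        design, truth, calls = noise_free
        for name, hybrids in design.combinations.items():
            h1, h2 = hybrids
            digs = isets.detect_digs(calls, design, h1, h2)
            planted = set(
                truth.dig_table.query("combination == @name")["gene_id"]
            )
            assert set(digs["gene_id"]) == planted
            # origin labels match the planted inheritance
            origins = truth.dig_table.query(
                "combination == @name and hybrid == @h1"
            ).set_index("gene_id")["origin"]
            got = digs.set_index("gene_id")[f"origin_{h1}"]
            assert (got == origins.loc[got.index]).all()

    def test_set_identities(self, noise_free):
        design, _, calls = noise_free
        ledger = isets.build_deg_ledger(calls, design)
        for name, (h1, h2) in design.combinations.items():
            digs = isets.detect_digs(calls, design, h1, h2)
            hegs = ledger.sets[f"HEGs_{h1}_{h2}"]
            hp = ledger.sets[f"HP_{h1}_{h2}"]
            pegs = ledger.sets[f"PEGs_{name}"]
            assert set(digs["gene_id"]) <= hegs
            assert hp == hegs & pegs
            if hp:
                ledger.add("tmp_hp", hp, "check")
                assert isets.overlap_fraction(ledger, "tmp_hp", f"HEGs_{h1}_{h2}") == 100.0

    def test_copdeg_direction_consistency(self, noise_free):
        design, _, calls = noise_free
        ledger = isets.build_deg_ledger(calls, design)
        for hybrid in design.hybrids:
            mat, pat = design.parents_of(hybrid)
            d1 = isets.get_calls(calls, hybrid, mat).set_index("gene_id")["direction"]
            d2 = isets.get_calls(calls, hybrid, pat).set_index("gene_id")["direction"]
            for gene, direction in ledger.directions[f"copDEGs_{hybrid}"].items():
                if direction in ("up", "down"):
                    assert d1[gene] == direction and d2[gene] == direction
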