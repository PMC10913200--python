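"""DEG set decomposition: PEGs, hybrid-parent DEGs, copDEGs, HEGs, H&P, DIGs.

Set vocabulary (per crossing combination of reciprocal hybrids):

- PEGs: genes differentially expressed between the two parents.
- DEGs(h vs p): genes DE between hybrid h and parent p.
- copDEGs(h): genes DE between h and *both* of its parents, with the
  direction recorded (up / down when concordant vs both, else conflicting).
- HEGs(h1, h2): genes DE between two hybrids.
- H&P: the intersection HEGs ∩ PEGs.
- DIGs(h1, h2): differentially inherited genes -- the hybrids differ from
  each other while each matches (is not DE from) exactly one parent, and
  those matched parents differ; the matched parent is the gene's origin.

Overlap percentages are asymmetric: 100 * |A ∩ B| / |A| with the
first-named set as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .io_formats import TriadDesign, ValidationError

CallSet = Mapping[tuple[str, str], pd.DataFrame]

_FLIP = {"up": "down", "down": "up", "ns": "ns"}


def get_calls(calls: CallSet, group_a: str, group_b: str) -> pd.DataFrame:
    """Calls for (group_a vs group_b), flipping a stored reverse comparison
    (antisymmetry of the pairwise test makes the flip exact)."""
    if (group_a, group_b) in calls:
        return calls[(group_a, group_b)]
    if (group_b, group_a) in calls:
        rev = calls[(group_b, group_a)].copy()
        rev["log2fc"] = -rev["log2fc"]
        rev["direction"] = rev["direction"].map(_FLIP)
        rev["group_a"], rev["group_b"] = group_a, group_b
        return rev
    raise ValidationError(f"missing required comparison {group_a} vs {group_b}")


def _de_genes(calls: pd.DataFrame) -> frozenset:
    return frozenset(calls.loc[calls["direction"] != "ns", "gene_id"])


@dataclass
class GeneSetLedger:
    """Named gene sets with provenance and direction metadata."""

    sets: dict[str, frozenset] = field(default_factory=dict)
    directions: dict[str, dict[str, str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes, provenance: str, directions=None) -> None:
        self.sets[name] = frozenset(genes)
        self.provenance[name] = provenance
        if directions is not None:
            self.directions[name] = dict(directions)

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            {
                "set_name": name,
                "gene_id": gene,
                "direction": self.directions.get(name, {}).get(gene, ""),
            }
            for name in sorted(self.sets)
            for gene in sorted(self.sets[name])
        ]
        return pd.DataFrame(rows, columns=["set_name", "gene_id", "direction"])

    def overlap_frame(self) -> pd.DataFrame:
        rows = []
        for a in sorted(self.sets):
            for b in sorted(self.sets):
                if a == b or not self.sets[a]:
                    continue
                rows.append(
                    {
                        "set_a": a,
                        "set_b": b,
                        "size_a": len(self.sets[a]),
                        "overlap": len(self.sets[a] & self.sets[b]),
                        "percent_of_a": overlap_fraction(self, a, b),
                    }
                )
        return pd.DataFrame(
            rows, columns=["set_a", "set_b", "size_a", "overlap", "percent_of_a"]
        )


def build_deg_ledger(calls: CallSet, design: TriadDesign) -> GeneSetLedger:
    """Assemble the per-combination DEG ledger from pairwise calls.

    Requires, per crossing combination: the parent-parent comparison, every
    hybrid-parent comparison, and the hybrid-hybrid comparison between the
    reciprocal hybrids.  Any hybrid-hybrid comparison present in *calls*
    across combinations is ledgered too (HEGs and H&P against the union of
    the two combinations' PEGs).
    """
    ledger = GeneSetLedger()
    combo_pegs: dict[str, frozenset] = {}
    for name, hybrids in design.combinations.items():
        pa, pb = design.combination_parents(name)
        pegs = _de_genes(get_calls(calls, pa, pb))
        combo_pegs[name] = pegs
        ledger.add(f"PEGs_{name}", pegs, f"DE {pa} vs {pb}")
        for hybrid in hybrids:
            mat, pat = design.parents_of(hybrid)
            per_parent = {}
            for parent in (mat, pat):
                c = get_calls(calls, hybrid, parent)
                per_parent[parent] = c.set_index("gene_id")["direction"]
                ledger.add(
                    f"DEGs_{hybrid}_vs_{parent}",
                    _de_genes(c),
                    f"DE {hybrid} vs {parent}",
                )
            d1, d2 = per_parent[mat], per_parent[pat]
            cop = d1.index[(d1 != "ns") & (d2 != "ns")]
            directions = {
                g: (d1[g] if d1[g] == d2[g] else "conflicting") for g in cop
            }
            ledger.add(
                f"copDEGs_{hybrid}",
                cop,
                f"DE {hybrid} vs both {mat} and {pat}",
                directions=directions,
            )
    # hybrid-hybrid comparisons present in the call set
    hybrids = set(design.hybrids)
    seen = set()
    for a, b in list(calls):
        pair = tuple(sorted((a, b)))
        if pair in seen or not (a in hybrids and b in hybrids):
            continue
        seen.add(pair)
        h1, h2 = pair
        hegs = _de_genes(get_calls(calls, h1, h2))
        ledger.add(f"HEGs_{h1}_{h2}", hegs, f"DE {h1} vs {h2}")
        names = {design.combination_of(h1), design.combination_of(h2)}
        pegs = frozenset().union(*(combo_pegs[n] for n in names))
        ledger.add(
            f"HP_{h1}_{h2}",
            hegs & pegs,
            f"HEGs_{h1}_{h2} ∩ PEGs of {sorted(names)}",
        )
    return ledger


def detect_digs(
    calls: CallSet, design: TriadDesign, hybrid_x: str, hybrid_y: str
) -> pd.DataFrame:
    """Differentially inherited genes between two hybrids, with origins.

    A gene qualifies iff (i) it is DE between the hybrids, (ii) each hybrid
    is ns versus exactly one of its own parents (and DE versus the other),
    and (iii) the two matched parents differ.
    """
    heg = get_calls(calls, hybrid_x, hybrid_y)
    matched: dict[str, pd.Series] = {}
    for hybrid in (hybrid_x, hybrid_y):
        mat, pat = design.parents_of(hybrid)
        d_m = get_calls(calls, hybrid, mat).set_index("gene_id")["direction"]
        d_p = get_calls(calls, hybrid, pat).set_index("gene_id")["direction"]
        origin = pd.Series("", index=d_m.index, dtype=object)
        origin[(d_m == "ns") & (d_p != "ns")] = mat
        origin[(d_m != "ns") & (d_p == "ns")] = pat
        matched[hybrid] = origin
    de_genes = heg.loc[heg["direction"] != "ns", "gene_id"]
    ox = matched[hybrid_x].reindex(de_genes)
    oy = matched[hybrid_y].reindex(de_genes)
    keep = (ox != "") & (oy != "") & (ox != oy)
    return pd.DataFrame(
        {
            "gene_id": de_genes[keep.to_numpy()].to_numpy(),
            f"origin_{hybrid_x}": ox[keep].to_numpy(),
            f"origin_{hybrid_y}": oy[keep].to_numpy(),
        }
    ).reset_index(drop=True)


def overlap_fraction(ledger: GeneSetLedger, name_a: str, name_b: str) -> float:
    """100 * |A ∩ B| / |A|, to two decimals; undefined (error) for empty A."""
    for name in (name_a, name_b):
        if name not in ledger.sets:
            raise ValidationError(f"set {name!r} not in ledger")
    a, b = ledger.sets[name_a], ledger.sets[name_b]
    if not a:
        raise ValidationError(f"overlap undefined: set {name_a!r} is empty")
    return round(100.0 * len(a & b) / len(a), 2)


def maternal_attribution(digs: pd.DataFrame, design: TriadDesign) -> pd.DataFrame:
    """Fraction of DIG origins that are the maternal parent, per hybrid
    plus a pooled 'combined' row; NaN-flagged when there are no DIGs."""
    origin_cols = [c for c in digs.columns if c.startswith("origin_")]
    if len(origin_cols) != 2:
        raise ValidationError("DIG table must carry two origin columns")
    rows = []
    pooled_maternal = pooled_total = 0
    for col in origin_cols:
        hybrid = col.removeprefix("origin_")
        maternal = design.parents_of(hybrid)[0]
        origins = digs[col]
        if origins.isin(["", None]).any() or origins.isna().any():
            raise ValidationError("DIG without origin label")
        n = len(origins)
        k = int((origins == maternal).sum())
        rows.append(
            {
                "hybrid": hybrid,
                "n_digs": n,
                "maternal_fraction": (k / n) if n else float("nan"),
            }
        )
        pooled_maternal += k
        pooled_total += n
    rows.append(
        {
            "hybrid": "combined",
            "n_digs": pooled_total,
            "maternal_fraction": (pooled_maternal / pooled_total)
            if pooled_total
            else float("nan"),
        }
    )
    return pd.DataFrame(rows)
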