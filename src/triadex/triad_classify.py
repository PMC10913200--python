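"""The 14-subcategory expression-remodeling classification of hybrid triads.

Each gene in a triad (parents A, B and their hybrid F1) yields three
pairwise DE relations -- A vs B, F1 vs A, F1 vs B -- giving 27 possible
patterns.  These map onto fourteen subcategories in five major categories:

=============  ==========================  =======================================
subcategories  major category              meaning
=============  ==========================  =======================================
1, 6           OPG (over-parent)           transgressive up/down from DE-conserved
                                           parents
2, 3 / 7, 8    OPG (over-parent)           transgressive beyond the higher / lower
                                           parent when the parents differ
4, 5 / 9, 10   BPG (biased-parent)         high- / low-parent dominance: F1 equals
                                           one parent and differs from the other
11, 12         AEG (additive)              F1 strictly intermediate between
                                           differing parents
13             conserved                   no significant difference anywhere
14             other                       every remaining (contradictory) pattern
=============  ==========================  =======================================

Subcategories 1-10 are the non-additively expressed genes (NEGs).  Parents
A and B are the *canonical* (sorted) parent pair of the crossing
combination, shared by both reciprocal hybrids, so a gene's subcategory is
directly comparable between F(AxB) and F(BxA).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Literal

import pandas as pd

from . import de_core
from .io_formats import ExpressionMatrix, TriadDesign, ValidationError

ParentRel = Literal["A_gt_B", "A_lt_B", "ns"]
Rel = Literal["gt", "lt", "ns"]

PARENT_RELS: tuple[ParentRel, ...] = ("A_gt_B", "A_lt_B", "ns")
RELS: tuple[Rel, ...] = ("gt", "lt", "ns")


@dataclass(frozen=True)
class PatternCode:
    """One of the 27 joint DE patterns of a triad."""

    parent_rel: ParentRel
    f1_vs_a: Rel
    f1_vs_b: Rel

    def __post_init__(self) -> None:
        if self.parent_rel not in PARENT_RELS:
            raise ValueError(f"invalid parent relation {self.parent_rel!r}")
        if self.f1_vs_a not in RELS or self.f1_vs_b not in RELS:
            raise ValueError("invalid F1-parent relation")

    def as_tuple(self) -> tuple[str, str, str]:
        return (self.parent_rel, self.f1_vs_a, self.f1_vs_b)


# The thirteen resolvable patterns; everything else is subcategory 14.
_NAMED_PATTERNS: dict[tuple[str, str, str], int] = {
    ("ns", "gt", "gt"): 1,
    ("A_gt_B", "gt", "gt"): 2,
    ("A_lt_B", "gt", "gt"): 3,
    ("A_gt_B", "ns", "gt"): 4,
    ("A_lt_B", "gt", "ns"): 5,
    ("ns", "lt", "lt"): 6,
    ("A_gt_B", "lt", "lt"): 7,
    ("A_lt_B", "lt", "lt"): 8,
    ("A_gt_B", "lt", "ns"): 9,
    ("A_lt_B", "ns", "lt"): 10,
    ("A_gt_B", "lt", "gt"): 11,
    ("A_lt_B", "gt", "lt"): 12,
    ("ns", "ns", "ns"): 13,
}

SUBCATEGORY_TABLE: dict[tuple[str, str, str], int] = {
    pattern: _NAMED_PATTERNS.get(pattern, 14)
    for pattern in product(PARENT_RELS, RELS, RELS)
}

MAJOR_OF_SUBCATEGORY: dict[int, str] = {
    **{c: "OPG" for c in (1, 2, 3, 6, 7, 8)},
    **{c: "BPG" for c in (4, 5, 9, 10)},
    **{c: "AEG" for c in (11, 12)},
    13: "conserved",
    14: "other",
}

NEG_SUBCATEGORIES = frozenset(range(1, 11))

# The parent the hybrid's expression matches in the dominance classes.
BIASED_PARENT: dict[int, str] = {4: "A", 5: "B", 9: "B", 10: "A"}

# Relabeling parents A<->B permutes the subcategories.
PARENT_SWAP_PERMUTATION: dict[int, int] = {
    1: 1, 2: 3, 3: 2, 4: 5, 5: 4, 6: 6, 7: 8, 8: 7,
    9: 10, 10: 9, 11: 12, 12: 11, 13: 13, 14: 14,
}

# Hyper/hypo duality: reflecting the hybrid about the parents (negate all
# contrasts, then relabel parents so the higher parent keeps its role)
# exchanges each hyper subcategory with its hypo counterpart.
HYPER_HYPO_DUAL: dict[int, int] = {
    1: 6, 2: 7, 3: 8, 4: 9, 5: 10, 6: 1, 7: 2, 8: 3,
    9: 4, 10: 5, 11: 11, 12: 12, 13: 13, 14: 14,
}

_PARENT_REL_FROM_DIRECTION = {"up": "A_gt_B", "down": "A_lt_B", "ns": "ns"}
_REL_FROM_DIRECTION = {"up": "gt", "down": "lt", "ns": "ns"}


def pattern_from_calls(call_pp: pd.Series, call_fa: pd.Series, call_fb: pd.Series) -> PatternCode:
    """Assemble a PatternCode from one gene's three DE call records.

    ``call_pp`` compares parent A vs parent B (direction 'up' means A > B);
    ``call_fa``/``call_fb`` compare the hybrid against each parent.
    """
    genes = {call_pp["gene_id"], call_fa["gene_id"], call_fb["gene_id"]}
    if len(genes) != 1:
        raise ValidationError(f"calls refer to different genes: {sorted(genes)}")
    return PatternCode(
        parent_rel=_PARENT_REL_FROM_DIRECTION[call_pp["direction"]],
        f1_vs_a=_REL_FROM_DIRECTION[call_fa["direction"]],
        f1_vs_b=_REL_FROM_DIRECTION[call_fb["direction"]],
    )


def class_from_pattern(pattern: PatternCode) -> tuple[int, str, str]:
    """(subcategory, major category, biased parent) for a pattern; total
    over all 27 patterns."""
    sub = SUBCATEGORY_TABLE[pattern.as_tuple()]
    return sub, MAJOR_OF_SUBCATEGORY[sub], BIASED_PARENT.get(sub, "none")


def classify_calls(
    calls_pp: pd.DataFrame, calls_fa: pd.DataFrame, calls_fb: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized classification of aligned call tables (same gene order)."""
    if not (
        calls_pp["gene_id"].equals(calls_fa["gene_id"])
        and calls_pp["gene_id"].equals(calls_fb["gene_id"])
    ):
        raise ValidationError("call tables are not aligned on the same genes")
    patterns = zip(
        calls_pp["direction"].map(_PARENT_REL_FROM_DIRECTION),
        calls_fa["direction"].map(_REL_FROM_DIRECTION),
        calls_fb["direction"].map(_REL_FROM_DIRECTION),
    )
    subs = [SUBCATEGORY_TABLE[p] for p in patterns]
    return pd.DataFrame(
        {
            "gene_id": calls_pp["gene_id"],
            "subcategory": subs,
            "major": [MAJOR_OF_SUBCATEGORY[s] for s in subs],
            "biased_parent": [BIASED_PARENT.get(s, "none") for s in subs],
        }
    ).reset_index(drop=True)


def classify_hybrid(
    matrix: ExpressionMatrix,
    design: TriadDesign,
    hybrid: str,
    method: str = "welch_log",
    pseudocount: float = 1.0,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Classify every gene of *hybrid*'s triad from replicate expression.

    Parent A / parent B are the canonical (sorted) parent pair of the
    hybrid's crossing combination.
    """
    if hybrid not in design.hybrids:
        raise ValidationError(f"{hybrid!r} is not a declared hybrid")
    pa, pb = design.triad_parents(hybrid)
    kwargs = dict(
        method=method,
        pseudocount=pseudocount,
        p_threshold=p_threshold,
        lfc_threshold=lfc_threshold,
    )
    calls_pp = de_core.test_pair(matrix, design, pa, pb, **kwargs)
    calls_fa = de_core.test_pair(matrix, design, hybrid, pa, **kwargs)
    calls_fb = de_core.test_pair(matrix, design, hybrid, pb, **kwargs)
    out = classify_calls(calls_pp, calls_fa, calls_fb)
    out.insert(1, "hybrid", hybrid)
    out.insert(2, "parent_a", pa)
    out.insert(3, "parent_b", pb)
    return out


def classify_from_means(
    means: pd.DataFrame,
    parent_a: str,
    parent_b: str,
    hybrid: str,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Threshold-only classification from a genotype-mean matrix
    (genes x genotypes); used for noise-free checks and for genotype-level
    methylation where no replicates exist."""
    calls_pp = de_core.calls_from_means(
        means[parent_a], means[parent_b], parent_a, parent_b,
        pseudocount=pseudocount, lfc_threshold=lfc_threshold,
    )
    calls_fa = de_core.calls_from_means(
        means[hybrid], means[parent_a], hybrid, parent_a,
        pseudocount=pseudocount, lfc_threshold=lfc_threshold,
    )
    calls_fb = de_core.calls_from_means(
        means[hybrid], means[parent_b], hybrid, parent_b,
        pseudocount=pseudocount, lfc_threshold=lfc_threshold,
    )
    out = classify_calls(calls_pp, calls_fa, calls_fb)
    out.insert(1, "hybrid", hybrid)
    out.insert(2, "parent_a", parent_a)
    out.insert(3, "parent_b", parent_b)
    return out


def reciprocal_consistent(
    assign_f_ab: pd.DataFrame, assign_f_ba: pd.DataFrame
) -> pd.DataFrame:
    """Genes with the identical remodeling subcategory in both reciprocal
    hybrids (ReCGs); doubly-conserved genes (subcategory 13 in both) are
    excluded since they exhibit no remodeling."""
    if set(assign_f_ab["gene_id"]) != set(assign_f_ba["gene_id"]):
        raise ValidationError("reciprocal assignments cover different gene universes")
    merged = assign_f_ab.merge(
        assign_f_ba[["gene_id", "subcategory"]], on="gene_id", suffixes=("", "_recip")
    )
    keep = (merged["subcategory"] == merged["subcategory_recip"]) & (
        merged["subcategory"] != 13
    )
    out = merged.loc[keep, ["gene_id", "subcategory", "major", "biased_parent"]]
    return out.reset_index(drop=True)


def summarize_classes(assignments: pd.DataFrame) -> pd.DataFrame:
    """Counts per subcategory (1..14, zero-filled) and per major category."""
    counts = assignments["subcategory"].value_counts().reindex(range(1, 15), fill_value=0)
    return pd.DataFrame(
        {
            "subcategory": counts.index,
            "major": [MAJOR_OF_SUBCATEGORY[s] for s in counts.index],
            "n_genes": counts.to_numpy(),
        }
    )
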