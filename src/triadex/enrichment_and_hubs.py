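"""Hypergeometric term enrichment and the focal-process hub-gene screen.

Enrichment is the classical one-sided (upper tail) hypergeometric test of
a study set against a background universe, BH-corrected over the tested
terms; a term passes at padj < 0.05 with at least 5 study hits.

The hub screen targets genes from four focal processes (photosynthesis
GO:0015979, pigment biosynthesis GO:0046148, rhythmic process GO:0048511,
starch metabolism GO:0005982) whose expression (i) is remodeled in at
least one hybrid, (ii) is balanced between reciprocal hybrids, and
(iii) differs between the two crossing combinations.  The ratio criteria
are interpreted as bounds on |log2 ratio| (|log2(E_rec1/E_rec2)| < 1,
|log2(E_comb1/E_comb2)| > 1); a literal raw-ratio mode is available for
comparison but is near-degenerate (an absolute raw ratio is almost always
> 1 or < 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de_core import bh_adjust
from .io_formats import ValidationError

PASS_PADJ = 0.05
PASS_MIN_COUNT = 5


def _term_sets(term_map: pd.DataFrame) -> dict[str, frozenset]:
    if not {"term", "gene_id"} <= set(term_map.columns):
        raise ValidationError("term map needs columns 'term' and 'gene_id'")
    return {
        term: frozenset(group["gene_id"])
        for term, group in term_map.groupby("term", sort=True)
    }


def enrich_terms(
    study_set, background, term_map: pd.DataFrame,
    padj_threshold: float = PASS_PADJ, min_count: int = PASS_MIN_COUNT,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of *study_set* per term.

    p = P(X >= k) for X ~ Hypergeom(N=|background|, K=|term ∩ background|,
    n=|study|); BH adjustment across the tested terms; ``pass`` enforces
    padj < 0.05 and k >= min_count.
    """
    study = frozenset(study_set)
    bg = frozenset(background)
    if offenders := sorted(study - bg):
        raise ValidationError(
            f"study genes absent from background: {offenders[:10]}"
        )
    n_study, n_bg = len(study), len(bg)
    rows = []
    for term, genes in _term_sets(term_map).items():
        term_bg = genes & bg
        k = len(genes & study)
        big_k = len(term_bg)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_study))
        rows.append(
            {"term": term, "k": k, "K": big_k, "n": n_study, "N": n_bg,
             "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["padj"] = []
        out["pass"] = []
        return out
    out["padj"] = bh_adjust(out["p_value"].to_numpy())
    out["pass"] = (out["padj"] < padj_threshold) & (out["k"] >= min_count)
    return out


def screen_hubs(
    class_tables: dict[str, pd.DataFrame],
    genotype_means: pd.DataFrame,
    term_map: pd.DataFrame,
    reciprocal_pair: tuple[str, str],
    other_pair: tuple[str, str],
    focal_terms=None,
    pseudocount: float = 1.0,
    reciprocal_max_log2: float = 1.0,
    combination_min_log2: float = 1.0,
    literal_ratio: bool = False,
) -> pd.DataFrame:
    """Screen focal-term genes for hub candidacy.

    Criteria (all required):

    1. remodeled (subcategory != 13) in at least one hybrid's class table;
    2. balanced between the reciprocal hybrids of *reciprocal_pair*:
       |log2 ratio| < ``reciprocal_max_log2``;
    3. differential between the two combinations:
       |log2(mean of reciprocal_pair / mean of other_pair)| >
       ``combination_min_log2``;
    4. annotated to at least one focal term.

    Ratios use genotype-mean expression with a pseudocount.  With
    ``literal_ratio`` the raw-ratio reading (|E1/E2| < 1, > 1) is applied
    instead of the log2-magnitude reading.
    """
    sets = _term_sets(term_map)
    if focal_terms is not None:
        sets = {t: s for t, s in sets.items() if t in set(focal_terms)}
    missing = [
        g for pair in (reciprocal_pair, other_pair) for g in pair
        if g not in genotype_means.columns
    ]
    if missing:
        raise ValidationError(f"missing genotype means for {missing}")

    h1, h2 = reciprocal_pair
    e1 = genotype_means[h1] + pseudocount
    e2 = genotype_means[h2] + pseudocount
    comb_a = genotype_means[list(reciprocal_pair)].mean(axis=1) + pseudocount
    comb_b = genotype_means[list(other_pair)].mean(axis=1) + pseudocount
    rec_log2 = np.log2(e1 / e2)
    comb_log2 = np.log2(comb_a / comb_b)
    if literal_ratio:
        crit2 = (e1 / e2).abs() < 1
        crit3 = (comb_a / comb_b).abs() > 1
    else:
        crit2 = rec_log2.abs() < reciprocal_max_log2
        crit3 = comb_log2.abs() > combination_min_log2

    sub_by_hybrid = {
        hybrid: table.set_index("gene_id")["subcategory"]
        for hybrid, table in class_tables.items()
    }
    remodeled = pd.Series(False, index=genotype_means.index)
    for subs in sub_by_hybrid.values():
        remodeled |= subs.reindex(genotype_means.index).fillna(13).ne(13)

    rows = []
    for term, genes in sorted(sets.items()):
        for gene in sorted(genes & set(genotype_means.index)):
            if not (remodeled[gene] and crit2[gene] and crit3[gene]):
                continue
            row = {
                "gene_id": gene,
                "focal_term": term,
                "reciprocal_log2_ratio": float(rec_log2[gene]),
                "combination_log2_ratio": float(comb_log2[gene]),
            }
            for hybrid in sorted(sub_by_hybrid):
                subs = sub_by_hybrid[hybrid].reindex([gene]).fillna(13)
                row[f"subcategory_{hybrid}"] = int(subs.iloc[0])
            rows.append(row)
    columns = [
        "gene_id", "focal_term", "reciprocal_log2_ratio", "combination_log2_ratio",
        *(f"subcategory_{h}" for h in sorted(class_tables)),
    ]
    return pd.DataFrame(rows, columns=columns)
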