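"""Linking immature-seed DNA methylation to seedling expression remodeling.

Sites are assigned, strand-aware, to gene regions (2 kb upstream of the
TSS, gene body, 2 kb downstream of the TES); regional methylation level is
the summed site RPM per genotype and context (an "amount"), with the
"all" context the exact sum of the two motif contexts.  Region levels are
correlated (Pearson, across genes) with expression, differential sites are
classified with the identical 27-pattern / 14-subcategory scheme used for
expression (major categories renamed OMS / BMS / AMS; NMS = 1-10), and
gene-level concordance matches a site's methylation subcategory against
the gene's expression subcategory: equal -> "consistent", hyper/hypo dual
(1<->6, 2<->7, 3<->8, 4<->9, 5<->10) -> "conflicting".
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import triad_classify
from .io_formats import (
    ExpressionMatrix,
    MethylationSiteTable,
    TriadDesign,
    ValidationError,
    validate_gene_models,
)

REGIONS = ("upstream2k", "body", "downstream2k")

MAJOR_TO_METH = {
    "OPG": "OMS", "BPG": "BMS", "AEG": "AMS",
    "conserved": "conserved", "other": "other",
}


def assign_regions(
    sites: MethylationSiteTable, genes: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Site -> (gene, region) assignments; strand decides which flank is
    upstream.  A site may hit several genes; sites hitting none are
    labeled intergenic (gene_id empty, region 'intergenic').
    """
    genes = validate_gene_models(genes)
    windows = []  # (chrom, lo, hi, gene, region)
    for row in genes.itertuples(index=False):
        plus = row.strand == "+"
        up = (max(1, row.start - flank), row.start - 1)
        down = (row.end + 1, row.end + flank)
        windows.append((row.chrom, row.start, row.end, row.gene_id, "body"))
        windows.append((row.chrom, *(up if plus else down), row.gene_id, "upstream2k"))
        windows.append((row.chrom, *(down if plus else up), row.gene_id, "downstream2k"))
    wdf = pd.DataFrame(windows, columns=["chrom", "lo", "hi", "gene_id", "region"])
    wdf = wdf[wdf["lo"] <= wdf["hi"]]

    out_rows = []
    site_df = sites.sites[["site_id", "chrom", "pos", "context"]]
    for chrom, chrom_sites in site_df.groupby("chrom", sort=True):
        cw = wdf[wdf["chrom"] == chrom]
        if cw.empty:
            for sid, ctx in zip(chrom_sites["site_id"], chrom_sites["context"]):
                out_rows.append((sid, ctx, "", "intergenic"))
            continue
        lo = cw["lo"].to_numpy()
        hi = cw["hi"].to_numpy()
        gid = cw["gene_id"].to_numpy()
        reg = cw["region"].to_numpy()
        for sid, pos, ctx in zip(
            chrom_sites["site_id"], chrom_sites["pos"], chrom_sites["context"]
        ):
            hits = np.where((lo <= pos) & (pos <= hi))[0]
            if hits.size == 0:
                out_rows.append((sid, ctx, "", "intergenic"))
            else:
                for j in hits:
                    out_rows.append((sid, ctx, gid[j], reg[j]))
    return pd.DataFrame(
        out_rows, columns=["site_id", "context", "gene_id", "region"]
    )


def region_level(
    sites: MethylationSiteTable, assignments: pd.DataFrame, agg: str = "sum"
) -> pd.DataFrame:
    """Aggregate RPM per (gene, region, context) and genotype.

    ``agg='sum'`` (default) totals site RPM -- the overall methylation
    amount of the region; ``agg='mean'`` averages per site.  The "all"
    context rows are the exact sum of the per-context rows, and regions
    with no sites are reported with level 0 for every context.
    """
    if agg not in ("sum", "mean"):
        raise ValueError(f"unknown aggregation {agg!r}")
    genic = assignments[assignments["region"] != "intergenic"]
    rpm = sites.rpm()
    merged = genic.merge(rpm, left_on="site_id", right_index=True)
    genotypes = list(sites.genotypes)
    grouped = (
        merged.groupby(["gene_id", "region", "context"])[genotypes]
        .agg(agg)
        .reset_index()
    )
    # complete the (gene x region x context) grid with zeros
    gene_ids = sorted(genic["gene_id"].unique())
    contexts = sorted(sites.sites["context"].unique())
    full = pd.MultiIndex.from_product(
        [gene_ids, REGIONS, contexts], names=["gene_id", "region", "context"]
    )
    grouped = (
        grouped.set_index(["gene_id", "region", "context"])
        .reindex(full, fill_value=0.0)
        .reset_index()
    )
    total = (
        grouped.groupby(["gene_id", "region"])[genotypes]
        .sum()
        .reset_index()
        .assign(context="all")
    )
    if agg == "mean":
        # "all" remains context-additive in the level sense only for sums;
        # for means, report the mean over all sites of the region instead
        total = (
            merged.groupby(["gene_id", "region"])[genotypes]
            .agg(agg)
            .reset_index()
            .assign(context="all")
        )
    out = pd.concat([grouped, total], ignore_index=True)
    return out[["gene_id", "region", "context", *genotypes]].sort_values(
        ["gene_id", "region", "context"], kind="stable", ignore_index=True
    )


def meth_expr_correlation(
    region_meth: pd.DataFrame,
    expression: ExpressionMatrix | pd.DataFrame,
    design: TriadDesign | None = None,
    mode: str = "gene_mean",
) -> pd.DataFrame:
    """Pearson r (and two-sided p) between methylation level and
    expression, per (region, context) -- 9 combinations.

    Expression is reduced to genotype means (given a replicate matrix and
    design) or taken as a genes x genotypes mean matrix directly.  With
    ``mode='gene_mean'`` both sides are averaged over genotypes and the
    correlation runs across genes; ``mode='pooled'`` correlates all
    (gene, genotype) pairs.
    """
    if isinstance(expression, ExpressionMatrix):
        if design is None:
            raise ValidationError("design required to reduce replicates")
        expr_means = expression.genotype_means(design)
    else:
        expr_means = expression
    genotypes = [c for c in region_meth.columns if c in expr_means.columns]
    if not genotypes:
        raise ValidationError("no shared genotypes between methylation and expression")
    rows = []
    for (region, context), sub in region_meth.groupby(["region", "context"], sort=True):
        sub = sub.set_index("gene_id")
        common = sub.index.intersection(expr_means.index)
        if len(common) < 3:
            raise ValidationError(
                f"({region}, {context}): fewer than 3 genes in common"
            )
        meth = sub.loc[common, genotypes]
        expr = expr_means.loc[common, genotypes]
        if mode == "gene_mean":
            x = expr.mean(axis=1).to_numpy()
            y = meth.mean(axis=1).to_numpy()
        elif mode == "pooled":
            x = expr.to_numpy().ravel()
            y = meth.to_numpy().ravel()
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if x.std() == 0 or y.std() == 0:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {"region": region, "context": context, "r": float(r),
             "p_value": float(p), "n_genes": len(common)}
        )
    return pd.DataFrame(rows)


def classify_dms(
    calls_pp: pd.DataFrame | None = None,
    calls_fa: pd.DataFrame | None = None,
    calls_fb: pd.DataFrame | None = None,
    *,
    site_rpm: pd.DataFrame | None = None,
    parent_a: str | None = None,
    parent_b: str | None = None,
    hybrid: str | None = None,
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-site remodeling classes via the shared 27-pattern scheme.

    Either supply the three differential-methylation call tables (the
    faithful mode when calls come from an upstream study), or supply
    genotype-level ``site_rpm`` (sites x genotypes) with the triad labels
    for threshold-only calls.  Output columns: site_id, subcategory,
    major (OMS/BMS/AMS/conserved/other).
    """
    if site_rpm is not None:
        if None in (parent_a, parent_b, hybrid):
            raise ValidationError("site_rpm mode requires parent_a, parent_b, hybrid")
        table = triad_classify.classify_from_means(
            site_rpm, parent_a, parent_b, hybrid,
            pseudocount=pseudocount, lfc_threshold=lfc_threshold,
        )
    else:
        if calls_pp is None or calls_fa is None or calls_fb is None:
            raise ValidationError(
                "classify_dms needs all three call tables (parent-parent, "
                "hybrid-parentA, hybrid-parentB)"
            )
        table = triad_classify.classify_calls(calls_pp, calls_fa, calls_fb)
        if hybrid is not None:
            table.insert(1, "hybrid", hybrid)
    table = table.rename(columns={"gene_id": "site_id"})
    table["major"] = table["major"].map(MAJOR_TO_METH)
    keep = [c for c in ("site_id", "hybrid", "subcategory", "major") if c in table]
    return table[keep]


def match_remodeling(
    expr_classes: pd.DataFrame,
    dms_classes: pd.DataFrame,
    assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Gene-level concordance of methylation vs expression remodeling.

    Per (gene, hybrid, context): ``consistent`` if any assigned site's
    methylation subcategory equals the gene's expression subcategory,
    ``conflicting`` if any site's subcategory is the hyper/hypo dual of
    it; a gene with several sites may carry both flags.  ``label``
    summarizes: both / consistent / conflicting / unmatched.  Sites
    mapped to no gene are skipped (count in ``attrs['n_intergenic']``).
    """
    dual = triad_classify.HYPER_HYPO_DUAL
    genic = assignments[assignments["region"] != "intergenic"]
    n_skipped = assignments["site_id"].nunique() - genic["site_id"].nunique()
    site_genes = genic[["site_id", "context", "gene_id"]].drop_duplicates()
    merged = site_genes.merge(dms_classes, on="site_id").merge(
        expr_classes[["gene_id", "hybrid", "subcategory"]],
        on=["gene_id", "hybrid"],
        suffixes=("_meth", "_expr"),
    )
    merged["consistent"] = merged["subcategory_meth"] == merged["subcategory_expr"]
    merged["conflicting"] = (
        merged["subcategory_meth"].map(dual) == merged["subcategory_expr"]
    ) & (merged["subcategory_meth"] != merged["subcategory_expr"])
    out = (
        merged.groupby(["gene_id", "hybrid", "context"])
        .agg(
            expr_subcategory=("subcategory_expr", "first"),
            n_sites=("site_id", "nunique"),
            consistent=("consistent", "any"),
            conflicting=("conflicting", "any"),
        )
        .reset_index()
    )
    label = np.select(
        [
            out["consistent"] & out["conflicting"],
            out["consistent"],
            out["conflicting"],
        ],
        ["both", "consistent", "conflicting"],
        default="unmatched",
    )
    out["label"] = label
    out.attrs["n_intergenic"] = int(n_skipped)
    return out


def feature_distribution(
    dms_classes: pd.DataFrame, assignments: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of sites falling in gene regions vs intergenic space, per
    remodeling class group (NMS = subcategories 1-10, AMS = 11-12,
    conserved = 13, other = 14); empty groups are NaN-flagged."""
    genic_ids = set(
        assignments.loc[assignments["region"] != "intergenic", "site_id"]
    )
    groups = {
        "NMS": range(1, 11), "AMS": (11, 12), "conserved": (13,), "other": (14,)
    }
    per_site = dms_classes.drop_duplicates(subset=["site_id", "hybrid"])
    rows = []
    for hybrid, sub in per_site.groupby("hybrid", sort=True):
        for name, cats in groups.items():
            members = sub[sub["subcategory"].isin(cats)]["site_id"]
            n = len(members)
            rows.append(
                {
                    "hybrid": hybrid,
                    "class_group": name,
                    "n_sites": n,
                    "gene_region_fraction": (
                        members.isin(genic_ids).mean() if n else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)
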