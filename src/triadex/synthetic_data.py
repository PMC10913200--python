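"""Synthetic parent/hybrid datasets with planted ground truth.

The generator emulates the study design the pipeline targets: three inbred
parents (P1, P2, P3), four hybrids from two reciprocal crossing
combinations sharing P1 (F12, F21, F13, F31), three biological replicates
per genotype.  It plants, per gene and crossing combination, one of the 14
remodeling subcategories; per methylation site, genotype RPM levels whose
region aggregates correlate with expression at configured signs; and per
trait, an exact population-level mid-parent heterosis percentage.

Counts follow a negative-binomial model (gene-wise base mean log-uniform,
constant dispersion), FPKM is derived as counts / (gene-length-kb x
library-size-millions), and all randomness flows from one seeded
generator, so identical configs and seeds give byte-identical tables.

Planted subcategories are constructed as exact offsets on the
log2(FPKM + pseudocount) scale -- the same scale on which the pipeline
measures fold changes -- so classifying the noise-free mean matrix
recovers every planted subcategory exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    MethylationSiteTable,
    TriadDesign,
    ValidationError,
    validate_phenotypes,
)
from . import triad_classify

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "MethylationTruth",
    "PhenotypeTruth",
    "generate_design",
    "generate_triad_dataset",
    "generate_gene_models",
    "generate_methylation",
    "generate_phenotypes",
    "generate_term_map",
    "FOCAL_TERMS",
]


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


#: The large majority of genes are not remodeled (conserved, subcategory
#: 13), matching observed pairwise DEG rates of a few to ~18% of the
#: transcriptome; among remodeled genes non-additive patterns dominate
#: (>90%) with biased-parent dominance (4, 5, 9, 10) the prevailing type
#: (~70%), and additive plus transgressive classes are minorities.
DEFAULT_CLASS_PROPORTIONS: dict[int, float] = {
    1: 0.008, 2: 0.006, 3: 0.006, 4: 0.030, 5: 0.030,
    6: 0.008, 7: 0.006, 8: 0.006, 9: 0.030, 10: 0.030,
    11: 0.006, 12: 0.006, 13: 0.820, 14: 0.008,
}

#: Coupling sign/magnitude of region-aggregate methylation with expression,
#: per (region, context): gene body positive in CCGG and negative in CCWGG,
#: the upstream flank opposite to the body, the downstream flank negative.
DEFAULT_COUPLINGS: dict[tuple[str, str], float] = {
    ("body", "CCGG"): 0.5,
    ("body", "CCWGG"): -0.3,
    ("upstream2k", "CCGG"): -0.5,
    ("upstream2k", "CCWGG"): 0.3,
    ("downstream2k", "CCGG"): -0.5,
    ("downstream2k", "CCWGG"): -0.3,
}

#: RPM aggregate (mean, sd) per context; CCGG (a CG motif) carries more
#: methylation signal than CCWGG, so the "all"-context correlation follows
#: the CCGG sign under the defaults.
DEFAULT_CONTEXT_SCALE: dict[str, tuple[float, float]] = {
    "CCGG": (10.0, 2.0),
    "CCWGG": (4.0, 1.0),
}

DEFAULT_TRAITS = (
    "seedling_height", "stem_thickness", "leaf_length",
    "leaf_width", "fresh_weight", "root_fresh_weight",
)

DEFAULT_PARENT_TRAIT_MEANS: dict[str, dict[str, float]] = {
    "P1": dict(zip(DEFAULT_TRAITS, (22.0, 2.8, 6.0, 3.5, 2.0, 0.90))),
    "P2": dict(zip(DEFAULT_TRAITS, (25.0, 3.0, 6.8, 4.0, 2.4, 1.10))),
    "P3": dict(zip(DEFAULT_TRAITS, (21.0, 2.7, 5.8, 3.4, 1.9, 0.85))),
}

#: Planted mid-parent heterosis (%) per hybrid x trait: the P1xP2
#: combination shows positive dominance in all six traits with fresh
#: weights above 30%, the P1xP3 combination is positive only in height.
DEFAULT_PHENOTYPE_MPH: dict[str, dict[str, float]] = {
    "F12": dict(zip(DEFAULT_TRAITS, (12.0, 10.0, 15.0, 15.0, 32.0, 35.0))),
    "F21": dict(zip(DEFAULT_TRAITS, (11.0, 9.0, 14.0, 14.0, 31.0, 33.0))),
    "F13": dict(zip(DEFAULT_TRAITS, (6.0, -2.0, -3.0, -4.0, -8.0, -6.0))),
    "F31": dict(zip(DEFAULT_TRAITS, (5.0, -2.5, -3.5, -4.5, -9.0, -7.0))),
}

FOCAL_TERMS = ("GO:0015979", "GO:0046148", "GO:0048511", "GO:0005982")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with study-design defaults."""

    n_genes: int = 2000
    replicates: int = 3
    class_proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    effect_size: float = 2.0          # planted |log2FC| for "different" relations
    dispersion: float = 0.05          # NB dispersion (var = mu + disp * mu^2)
    base_mean_range: tuple[float, float] = (5.0, 500.0)   # FPKM, log-uniform
    gene_length_range: tuple[int, int] = (500, 5000)      # bp
    library_scale: float = 10.0       # nominal library size, millions of fragments
    pseudocount: float = 1.0
    lfc_threshold: float = 1.0
    dig_proportion: float = 0.03   # reciprocal differential-inheritance genes
    dig_maternal_bias: float = 0.8  # P(origin parent is maternal for both)
    seed: int = 0
    parents: tuple[str, ...] = ("P1", "P2", "P3")
    parentage: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "F12": ("P1", "P2"), "F21": ("P2", "P1"),
            "F13": ("P1", "P3"), "F31": ("P3", "P1"),
        }
    )
    # methylation
    couplings: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS)
    )
    context_scale: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTEXT_SCALE)
    )
    sites_per_region: float = 0.8     # Poisson rate on top of 1 guaranteed site
    intergenic_site_rate: float = 0.5  # intergenic sites per gene
    flank: int = 2000                 # bp, upstream/downstream window
    # phenotypes
    traits: tuple[str, ...] = DEFAULT_TRAITS
    parent_trait_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_PARENT_TRAIT_MEANS.items()}
    )
    phenotype_mph: dict[str, dict[str, float]] = field(
        default_factory=lambda: {h: dict(v) for h, v in DEFAULT_PHENOTYPE_MPH.items()}
    )
    phenotype_cv: float = 0.05
    phenotype_replicates: int = 3

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class proportions sum to {total}, not 1")
        if set(self.class_proportions) - set(range(1, 15)):
            raise ConfigError("class proportions keyed outside subcategories 1..14")
        if (np.array(list(self.class_proportions.values())) < 0).any():
            raise ConfigError("negative class proportion")
        if self.effect_size <= 0 or self.dispersion <= 0:
            raise ConfigError("effect_size and dispersion must be positive")
        if self.effect_size <= self.lfc_threshold:
            nonconserved = any(
                p > 0 for c, p in self.class_proportions.items() if c != 13
            )
            if nonconserved:
                raise ConfigError(
                    "effect_size must exceed the log2FC threshold to realize "
                    "non-conserved subcategories"
                )
        if not (0 <= self.dig_proportion < 1):
            raise ConfigError("dig_proportion must lie in [0, 1)")
        if not (0 <= self.dig_maternal_bias <= 1):
            raise ConfigError("dig_maternal_bias must lie in [0, 1]")
        for (region, context), rho in self.couplings.items():
            if abs(rho) >= 1:
                raise ConfigError(
                    f"coupling magnitude for ({region}, {context}) must be < 1 "
                    "when noise is nonzero"
                )
        for hybrid, traits in self.phenotype_mph.items():
            mat, pat = self.parentage[hybrid]
            for trait in traits:
                for parent in (mat, pat):
                    if self.parent_trait_means[parent][trait] <= 0:
                        raise ConfigError(
                            f"parent {parent!r} mean for trait {trait!r} must be "
                            "positive for a ratio-based heterosis index"
                        )


@dataclass
class SyntheticTruth:
    """Planted expression ground truth."""

    class_table: pd.DataFrame       # gene_id, hybrid, subcategory, major
    mean_fpkm: pd.DataFrame         # genes x genotypes, planted noise-free means
    gene_lengths: pd.Series
    dig_table: pd.DataFrame         # combination, gene_id, hybrid, origin


@dataclass
class MethylationTruth:
    """Planted methylation ground truth."""

    expected_sign: pd.DataFrame     # region, context (incl. "all"), sign
    assignments: pd.DataFrame       # site_id, gene_id, region
    dms_class_table: pd.DataFrame   # site_id, hybrid, subcategory (threshold classes)


@dataclass
class PhenotypeTruth:
    """Planted phenotype ground truth."""

    heterosis: pd.DataFrame         # hybrid, trait, mph, bph, hybrid_mean, ...


# ---------------------------------------------------------------------------
# Design and expression


def generate_design(config: SimulationConfig) -> TriadDesign:
    roles = {p: "parent" for p in config.parents}
    roles.update({h: "hybrid" for h in config.parentage})
    sample_map = {}
    for genotype in sorted(roles):
        for rep in range(1, config.replicates + 1):
            sample_map[f"{genotype}_r{rep}"] = (genotype, rep)
    return TriadDesign(roles=roles, parentage=dict(config.parentage), sample_map=sample_map)


def _triad_offsets(sub: int, e: float, t: float) -> tuple[float, float]:
    """(offset of parent B, offset of F1) relative to parent A on the
    log2(FPKM + pseudocount) scale realizing subcategory *sub* exactly.

    Subcategory 14 has no transitive realization among the named patterns;
    it is planted through the resolvable-but-unnamed pattern (ns, gt, ns):
    parents sub-threshold apart, F1 above A but within threshold of B.
    """
    table = {
        1: (0.0, e), 2: (-e, e), 3: (e, 2 * e),
        4: (-e, 0.0), 5: (e, e),
        6: (0.0, -e), 7: (-e, -2 * e), 8: (e, -e),
        9: (-e, -e), 10: (e, 0.0),
        11: (-2 * e, -e), 12: (2 * e, e),
        13: (0.0, 0.0), 14: (0.6 * t, 1.55 * t),
    }
    return table[sub]


def _subcategory_from_latents(la: float, lb: float, lf: float, t: float) -> int:
    """Subcategory realized by a latent triple under strict threshold t."""

    def rel(x: float) -> str:
        return "gt" if x > t else ("lt" if x < -t else "ns")

    parent_rel = {"gt": "A_gt_B", "lt": "A_lt_B", "ns": "ns"}[rel(la - lb)]
    return triad_classify.SUBCATEGORY_TABLE[(parent_rel, rel(lf - la), rel(lf - lb))]


def generate_triad_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, TriadDesign, SyntheticTruth]:
    """Simulate counts/FPKM for the full seven-genotype design.

    One subcategory is planted per gene and crossing combination and shared
    by both reciprocal hybrids (they receive the identical planted mean),
    so reciprocal-consistency is exact in the noise-free truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = generate_design(config)
    n = config.n_genes
    genes = pd.Index([f"G{i + 1:05d}" for i in range(n)], name="gene_id")

    lo, hi = config.base_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    gene_lengths = pd.Series(lengths, index=genes, name="length")

    subs = np.array(sorted(config.class_proportions))
    probs = np.array([config.class_proportions[s] for s in subs], dtype=float)
    probs = probs / probs.sum()
    e, t, pc = config.effect_size, config.lfc_threshold, config.pseudocount

    combos: dict[str, list[str]] = {}
    for hybrid, (mat, pat) in config.parentage.items():
        combos.setdefault("x".join(sorted((mat, pat))), []).append(hybrid)
    for name in combos:
        combos[name] = sorted(combos[name])

    planted_sub = {name: rng.choice(subs, size=n, p=probs) for name in sorted(combos)}

    # latent log2(FPKM + pc) per genotype, anchored at the shared parent level
    latent = {g: np.empty(n) for g in design.genotypes}
    l_base = np.log2(base + pc)

    shared = {p for name in combos for p in name.split("x")}
    anchor_parent = sorted(
        shared, key=lambda p: (-sum(p in name.split("x") for name in combos), p)
    )[0]
    # per combination: offsets of the non-anchor parent and of each hybrid
    # relative to the anchor parent (planted offsets are relative to
    # canonical A, the sorted-first parent)
    d_other_by: dict[str, np.ndarray] = {}
    d_hyb_by: dict[str, dict[str, np.ndarray]] = {}
    dig_rows: list[dict] = []
    for name in sorted(combos):
        pa, pb = name.split("x")
        if anchor_parent not in (pa, pb):
            raise ConfigError(
                f"crossing combinations must share the anchor parent {anchor_parent!r}"
            )
        off = np.array([_triad_offsets(s, e, t) for s in planted_sub[name]])
        d_b, d_f = off[:, 0], off[:, 1]
        if pa != anchor_parent:  # anchor is canonical B: re-anchor
            d_b, d_f = -d_b, d_f - d_b
        d_other_by[name] = d_b.copy()
        d_hyb_by[name] = {h: d_f.copy() for h in combos[name]}

        # plant differential inheritance between the reciprocal hybrids:
        # parents DE, each hybrid matching a different parent's level; the
        # matched (origin) parent is maternal for both hybrids with
        # probability dig_maternal_bias, else paternal for both
        if config.dig_proportion > 0 and len(combos[name]) == 2:
            mask = rng.random(n) < config.dig_proportion
            idx = np.flatnonzero(mask)
            signs = rng.choice([-e, e], size=idx.size)
            maternal_joint = rng.random(idx.size) < config.dig_maternal_bias
            d_other_by[name][idx] = signs
            for hybrid in combos[name]:
                mat, pat = config.parentage[hybrid]
                origin_is_anchor = np.where(
                    maternal_joint, mat == anchor_parent, pat == anchor_parent
                )
                d_hyb_by[name][hybrid][idx] = np.where(origin_is_anchor, 0.0, signs)
                origins = np.where(maternal_joint, mat, pat)
                for gi, origin in zip(idx, origins):
                    dig_rows.append(
                        {
                            "combination": name,
                            "gene_id": f"G{gi + 1:05d}",
                            "hybrid": hybrid,
                            "origin": origin,
                        }
                    )

    # keep every planted mean non-negative on the FPKM scale
    floor = np.zeros(n)
    for name in sorted(combos):
        floor = np.minimum(floor, d_other_by[name])
        for d in d_hyb_by[name].values():
            floor = np.minimum(floor, d)
    l_min = np.log2(pc) if pc > 0 else 0.0
    l_anchor = np.maximum(l_base, l_min - floor)

    latent[anchor_parent] = l_anchor
    for name in sorted(combos):
        pa, pb = name.split("x")
        other = pb if pa == anchor_parent else pa
        latent[other] = l_anchor + d_other_by[name]
        for hybrid in combos[name]:
            latent[hybrid] = l_anchor + d_hyb_by[name][hybrid]

    # per-hybrid planted subcategories, derived from the realized latents
    # (DIG genes diverge from the combo draw; all others must reproduce it)
    dig_genes = {(row["combination"], row["gene_id"]) for row in dig_rows}
    planted_by_hybrid: dict[str, np.ndarray] = {}
    for name in sorted(combos):
        pa, pb = name.split("x")
        for hybrid in combos[name]:
            planted = np.array(
                [
                    _subcategory_from_latents(
                        latent[pa][gi], latent[pb][gi], latent[hybrid][gi], t
                    )
                    for gi in range(n)
                ]
            )
            drawn_ok = (planted == planted_sub[name]) | np.array(
                [(name, f"G{gi + 1:05d}") in dig_genes for gi in range(n)]
            )
            if not drawn_ok.all():
                raise RuntimeError(
                    f"planted offsets fail to realize the drawn subcategory for "
                    f"{int((~drawn_ok).sum())} genes in {hybrid}"
                )
            planted_by_hybrid[hybrid] = planted

    mean_fpkm = pd.DataFrame(
        {g: np.maximum(2.0 ** latent[g] - pc, 0.0) for g in design.genotypes},
        index=genes,
    )

    # NB counts per sample, FPKM from realized library sizes
    len_kb = lengths / 1000.0
    counts_cols = {}
    disp = config.dispersion
    for genotype in design.genotypes:
        mu = mean_fpkm[genotype].to_numpy() * len_kb * config.library_scale
        for sample in design.samples_of(genotype):
            p_nb = 1.0 / (1.0 + disp * mu)
            counts_cols[sample] = rng.negative_binomial(1.0 / disp, p_nb)
    counts = pd.DataFrame(counts_cols, index=genes)
    lib_millions = counts.sum(axis=0) / 1e6
    fpkm = counts / np.outer(len_kb, lib_millions)
    fpkm = pd.DataFrame(fpkm, index=genes, columns=counts.columns)

    rows = []
    for name in sorted(combos):
        for hybrid in combos[name]:
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "hybrid": hybrid,
                        "subcategory": planted_by_hybrid[hybrid],
                        "major": [
                            triad_classify.MAJOR_OF_SUBCATEGORY[s]
                            for s in planted_by_hybrid[hybrid]
                        ],
                    }
                )
            )
    dig_table = pd.DataFrame(
        dig_rows, columns=["combination", "gene_id", "hybrid", "origin"]
    )
    truth = SyntheticTruth(
        class_table=pd.concat(rows, ignore_index=True),
        mean_fpkm=mean_fpkm,
        gene_lengths=gene_lengths,
        dig_table=dig_table,
    )

    _check_consistency(truth, design, pc, t)
    matrix = ExpressionMatrix(fpkm=fpkm, counts=counts, gene_lengths=gene_lengths)
    return matrix, design, truth


def _check_consistency(
    truth: SyntheticTruth, design: TriadDesign, pseudocount: float, lfc_threshold: float
) -> None:
    """Generation-time contract: threshold-classifying the noise-free mean
    matrix must recover 100% of planted subcategories."""
    for hybrid in design.hybrids:
        pa, pb = design.triad_parents(hybrid)
        got = triad_classify.classify_from_means(
            truth.mean_fpkm, pa, pb, hybrid,
            pseudocount=pseudocount, lfc_threshold=lfc_threshold,
        )
        planted = truth.class_table.query("hybrid == @hybrid").set_index("gene_id")
        mismatch = (
            got.set_index("gene_id")["subcategory"] != planted["subcategory"]
        )
        if mismatch.any():
            raise RuntimeError(
                f"planted subcategories are not noise-free recoverable for "
                f"{hybrid}: {int(mismatch.sum())} mismatches"
            )


# ---------------------------------------------------------------------------
# Gene models and methylation


def generate_gene_models(
    gene_lengths: pd.Series, flank: int = 2000, genes_per_chrom: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Lay genes along synthetic chromosomes with gaps wide enough that
    flank windows never overlap a neighboring gene's windows."""
    rng = np.random.default_rng(seed)
    rows = []
    pos = flank + 1001
    chrom_i = 1
    for i, (gene, length) in enumerate(gene_lengths.items()):
        if i and i % genes_per_chrom == 0:
            chrom_i += 1
            pos = flank + 1001
        start = pos
        end = start + int(length) - 1
        rows.append(
            {
                "gene_id": gene,
                "chrom": f"Chr{chrom_i:02d}",
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
            }
        )
        pos = end + 2 * flank + 1001
    return pd.DataFrame(rows)


def generate_methylation(
    config: SimulationConfig,
    gene_models: pd.DataFrame,
    truth: SyntheticTruth,
) -> tuple[MethylationSiteTable, MethylationTruth]:
    """Per-site genotype RPM whose region aggregates correlate with
    expression at the configured sign per (region, context).

    The aggregate for gene g, genotype k is linear in the standardized
    planted expression of (g, k) plus gene-level Gaussian noise shared
    across genotypes, so the Pearson correlation across genes equals the
    configured coupling by construction; per-site RPM splits the aggregate
    by symmetric Dirichlet weights shared across genotypes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    expr = truth.mean_fpkm
    genotypes = list(expr.columns)
    z = (expr - expr.mean(axis=0)) / expr.std(axis=0)
    n = len(expr)
    gm = gene_models.set_index("gene_id")

    records: list[dict] = []
    assign_rows: list[dict] = []
    regions = ("upstream2k", "body", "downstream2k")
    contexts = tuple(config.context_scale)
    for region in regions:
        for context in contexts:
            rho = config.couplings.get((region, context), 0.0)
            mu, sd = config.context_scale[context]
            eps = rng.standard_normal(n)
            agg = mu + sd * (rho * z.to_numpy() + np.sqrt(1 - rho**2) * eps[:, None])
            agg = np.clip(agg, 0.0, None)
            if config.sites_per_region <= 0:
                continue
            n_sites = 1 + rng.poisson(config.sites_per_region, size=n)
            for gi, gene in enumerate(expr.index):
                row = gm.loc[gene]
                lo_b, hi_b = _region_bounds(row, region, config.flank)
                k = min(n_sites[gi], hi_b - lo_b + 1)
                positions = np.sort(rng.choice(np.arange(lo_b, hi_b + 1), size=k, replace=False))
                weights = rng.dirichlet(np.ones(k))
                for pos, w in zip(positions, weights):
                    rec = {"chrom": row["chrom"], "pos": int(pos), "context": context}
                    for kk, genotype in enumerate(genotypes):
                        rec[genotype] = round(float(w * agg[gi, kk]), 6)
                    records.append(rec)
                    assign_rows.append(
                        {
                            "site_id": f"{row['chrom']}:{int(pos)}:{context}",
                            "gene_id": gene,
                            "region": region,
                        }
                    )

    # uncoupled intergenic background sites
    n_inter = int(config.intergenic_site_rate * n)
    ordered = gene_models.sort_values(["chrom", "start"], kind="stable")
    gaps = []
    for chrom, sub in ordered.groupby("chrom", sort=True):
        bounds = sub[["start", "end"]].to_numpy()
        for (s1, e1), (s2, _e2) in zip(bounds[:-1], bounds[1:]):
            lo_g = e1 + config.flank + 1
            hi_g = s2 - config.flank - 1
            if hi_g > lo_g:
                gaps.append((chrom, (lo_g + hi_g) // 2))
    for i in range(min(n_inter, len(gaps))):
        chrom, pos = gaps[i]
        context = contexts[i % len(contexts)]
        mu, sd = config.context_scale[context]
        level = max(0.0, rng.normal(mu, sd))
        rec = {"chrom": chrom, "pos": int(pos), "context": context}
        for genotype in genotypes:
            rec[genotype] = round(max(0.0, level + rng.normal(0, 0.1 * sd)), 6)
        records.append(rec)

    df = pd.DataFrame(records)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "pos", "context", *genotypes])
    df = df.drop_duplicates(subset=["chrom", "pos", "context"], keep="first")
    df.insert(0, "site_id", df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":" + df["context"])
    table = MethylationSiteTable(sites=df.reset_index(drop=True), genotypes=tuple(genotypes))

    sign_rows = []
    for region in regions:
        num = 0.0
        for context in contexts:
            rho = config.couplings.get((region, context), 0.0)
            sign_rows.append(
                {"region": region, "context": context, "sign": int(np.sign(rho))}
            )
            num += rho * config.context_scale[context][1]
        sign_rows.append({"region": region, "context": "all", "sign": int(np.sign(num))})

    assignments = pd.DataFrame(
        assign_rows, columns=["site_id", "gene_id", "region"]
    )
    assignments = assignments[assignments["site_id"].isin(df["site_id"])].reset_index(drop=True)
    dms_classes = _threshold_site_classes(table, config)
    truth_m = MethylationTruth(
        expected_sign=pd.DataFrame(sign_rows),
        assignments=assignments,
        dms_class_table=dms_classes,
    )
    return table, truth_m


def _region_bounds(gene_row: pd.Series, region: str, flank: int) -> tuple[int, int]:
    start, end, strand = int(gene_row["start"]), int(gene_row["end"]), gene_row["strand"]
    if region == "body":
        return start, end
    upstream = (region == "upstream2k")
    if (strand == "+") == upstream:
        return max(1, start - flank), max(1, start - 1)
    return end + 1, end + flank


def _threshold_site_classes(
    table: MethylationSiteTable, config: SimulationConfig
) -> pd.DataFrame:
    """Deterministic per-site remodeling classes from genotype-level RPM,
    recorded as the planted DMS truth."""
    rpm = table.rpm()
    if rpm.empty:
        return pd.DataFrame(columns=["site_id", "hybrid", "subcategory", "major"])
    out = []
    for hybrid, (mat, pat) in sorted(config.parentage.items()):
        pa, pb = sorted((mat, pat))
        classes = triad_classify.classify_from_means(
            rpm, pa, pb, hybrid,
            pseudocount=config.pseudocount, lfc_threshold=config.lfc_threshold,
        )
        classes = classes.rename(columns={"gene_id": "site_id"})
        out.append(classes[["site_id", "hybrid", "subcategory", "major"]])
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Phenotypes


def generate_phenotypes(
    config: SimulationConfig, design: TriadDesign
) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Replicate trait values whose population means realize the planted
    MPH exactly; replicate noise is Gaussian with the configured CV."""
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    means: dict[tuple[str, str], float] = {}
    for parent in config.parents:
        for trait in config.traits:
            means[(parent, trait)] = config.parent_trait_means[parent][trait]
    truth_rows = []
    for hybrid in sorted(config.parentage):
        mat, pat = config.parentage[hybrid]
        for trait in config.traits:
            mid = 0.5 * (means[(mat, trait)] + means[(pat, trait)])
            best = max(means[(mat, trait)], means[(pat, trait)])
            mph = config.phenotype_mph[hybrid][trait]
            hybrid_mean = mid * (1 + mph / 100.0)
            means[(hybrid, trait)] = hybrid_mean
            truth_rows.append(
                {
                    "hybrid": hybrid,
                    "trait": trait,
                    "mph": mph,
                    "bph": 100.0 * (hybrid_mean - best) / best,
                    "hybrid_mean": hybrid_mean,
                    "mid_parent": mid,
                    "best_parent": best,
                }
            )
    rows = []
    for genotype in design.genotypes:
        for trait in config.traits:
            m = means[(genotype, trait)]
            for rep in range(1, config.phenotype_replicates + 1):
                value = m * (1 + config.phenotype_cv * rng.standard_normal())
                rows.append(
                    {
                        "genotype": genotype,
                        "trait": trait,
                        "replicate": rep,
                        "value": round(float(value), 6),
                    }
                )
    pheno = validate_phenotypes(
        pd.DataFrame(rows), min_replicates=min(3, config.phenotype_replicates)
    )
    return pheno, PhenotypeTruth(heterosis=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# GO term map


def generate_term_map(
    genes,
    seed: int = 0,
    n_generic_terms: int = 16,
    focal_fraction: float = 0.03,
    enriched_genes=None,
    enrichment_weight: float = 0.5,
) -> pd.DataFrame:
    """A synthetic term -> gene map: the four focal processes plus generic
    terms, each a random draw from the gene universe.

    When *enriched_genes* is given, that share (``enrichment_weight``) of
    each focal term is drawn from it, planting genuine over-representation
    of the focal processes among those genes.
    """
    rng = np.random.default_rng(seed + 3)
    genes = pd.Index(genes)
    enriched = (
        pd.Index([]) if enriched_genes is None else pd.Index(enriched_genes)
    ).intersection(genes)
    rows = []
    for term in FOCAL_TERMS:
        size = min(max(5, int(focal_fraction * len(genes))), len(genes))
        n_enr = min(int(enrichment_weight * size), len(enriched))
        picked = list(rng.choice(enriched, size=n_enr, replace=False))
        rest = genes.difference(pd.Index(picked))
        picked += list(rng.choice(rest, size=size - n_enr, replace=False))
        for gene in picked:
            rows.append({"term": term, "gene_id": gene})
    for i in range(n_generic_terms):
        size = int(rng.integers(10, max(11, len(genes) // 10)))
        for gene in rng.choice(genes, size=min(size, len(genes)), replace=False):
            rows.append({"term": f"GO:9{i:06d}", "gene_id": gene})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
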