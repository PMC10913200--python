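"""End-to-end orchestration: simulate/load -> filter -> DE -> classify ->
sets -> heterosis -> enrichment/hubs -> methylation -> summary.

A single ``RunConfig`` (YAML-loadable) is the source of truth; the run is
fully deterministic under a fixed seed, and every output table carries a
provenance header with the package version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    de_core,
    enrichment_and_hubs,
    heterosis_metrics,
    inheritance_sets,
    io_formats,
    methylation_link,
    synthetic_data,
    triad_classify,
)
from .io_formats import ValidationError
from .synthetic_data import SimulationConfig


@dataclass
class RunConfig:
    """Pipeline configuration: either a simulation block or input paths."""

    seed: int = 0
    out_dir: str = "triadex_run"
    simulate: dict | None = None
    inputs: dict | None = None
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    fpkm_filter: float = 1.0
    pseudocount: float = 1.0
    enrich_padj: float = 0.05
    enrich_min_count: int = 5
    de_method: str = "welch_log"
    meth_agg: str = "sum"
    flank: int = 2000

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        thresholds = data.pop("thresholds", {})
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in data.items() if k in known})
        for key, attr in (
            ("p", "p_threshold"), ("lfc", "lfc_threshold"),
            ("fpkm_filter", "fpkm_filter"), ("enrich_padj", "enrich_padj"),
            ("enrich_min_count", "enrich_min_count"),
        ):
            if key in thresholds:
                setattr(cfg, attr, thresholds[key])
        if cfg.simulate is None and cfg.inputs is None:
            raise ValidationError(
                "config needs either a 'simulate' block or an 'inputs' block"
            )
        for name in ("p_threshold", "lfc_threshold", "fpkm_filter"):
            if getattr(cfg, name) <= 0:
                raise ValidationError(f"threshold {name} must be positive")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        blob = json.dumps(
            {
                k: getattr(self, k)
                for k in sorted(self.__dataclass_fields__)
                if k != "out_dir"
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _simulation_config(config: RunConfig) -> SimulationConfig:
    sim = dict(config.simulate or {})
    sim.setdefault("seed", config.seed)
    sim.setdefault("lfc_threshold", config.lfc_threshold)
    sim.setdefault("pseudocount", config.pseudocount)
    sim.setdefault("flank", config.flank)
    known = set(SimulationConfig.__dataclass_fields__)
    if unknown := set(sim) - known:
        raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationConfig(**sim)


def _required_pairs(design: io_formats.TriadDesign) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for name, hybrids in design.combinations.items():
        pa, pb = design.combination_parents(name)
        pairs.append((pa, pb))
        for hybrid in hybrids:
            pairs.extend([(hybrid, pa), (hybrid, pb)])
    hybrids = design.hybrids
    for i, h1 in enumerate(hybrids):
        for h2 in hybrids[i + 1:]:
            pairs.append((h1, h2))
    return pairs


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the result bundle under out_dir.

    Returns the bundle: tables keyed by name plus the machine-readable
    summary dict (also written as summary.json).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    command = f"run seed={config.seed} cfg={config.config_hash()}"
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash()}
    tables: dict[str, pd.DataFrame] = {}

    # ---- stage: data ------------------------------------------------------
    stage = "data"
    try:
        pheno = gene_models = sites = term_map = None
        truth = truth_m = truth_p = None
        if config.simulate is not None:
            sim = _simulation_config(config)
            matrix, design, truth = synthetic_data.generate_triad_dataset(sim)
            gene_models = synthetic_data.generate_gene_models(
                truth.gene_lengths, flank=sim.flank, seed=sim.seed
            )
            sites, truth_m = synthetic_data.generate_methylation(
                sim, gene_models, truth
            )
            pheno, truth_p = synthetic_data.generate_phenotypes(sim, design)
            remodeled = truth.class_table.loc[
                truth.class_table["subcategory"] != 13, "gene_id"
            ].unique()
            term_map = synthetic_data.generate_term_map(
                matrix.gene_ids, seed=sim.seed, enriched_genes=remodeled
            )
            io_formats.write_expression(matrix, out_dir / "expression_fpkm.tsv", command)
            io_formats.write_design(design, out_dir / "design.tsv", command)
            io_formats.write_gene_models(gene_models, out_dir / "gene_models.bed", command)
            io_formats.write_methylation_sites(sites, out_dir / "methylation_sites.tsv", command)
            io_formats.write_table(pheno, out_dir / "phenotypes.tsv", command)
            io_formats.write_table(term_map, out_dir / "term_map.tsv", command)
            io_formats.write_table(truth.class_table, out_dir / "truth_classes.tsv", command)
            io_formats.write_table(truth_p.heterosis, out_dir / "truth_heterosis.tsv", command)
        else:
            inputs = config.inputs or {}
            matrix = io_formats.read_expression(
                inputs["expression"], counts_path=inputs.get("counts"),
                lengths_path=inputs.get("gene_lengths"),
            )
            design = io_formats.read_design(inputs["design"])
            if "gene_models" in inputs:
                gene_models = io_formats.read_gene_models(inputs["gene_models"])
            if "methylation_sites" in inputs:
                sites = io_formats.read_methylation_sites(inputs["methylation_sites"])
            if "phenotypes" in inputs:
                pheno = io_formats.read_phenotypes(inputs["phenotypes"])
            if "term_map" in inputs:
                term_map = io_formats.read_table(inputs["term_map"])

        # ---- stage: filter + DE ------------------------------------------
        stage = "filter"
        filtered = de_core.filter_low_expression(matrix, design, config.fpkm_filter)
        summary["n_genes_input"] = int(len(matrix.gene_ids))
        summary["n_genes_filtered"] = int(len(filtered.gene_ids))

        stage = "de"
        de_kwargs = dict(
            method=config.de_method, pseudocount=config.pseudocount,
            p_threshold=config.p_threshold, lfc_threshold=config.lfc_threshold,
        )
        calls: dict[tuple[str, str], pd.DataFrame] = {}
        for a, b in _required_pairs(design):
            if (a, b) not in calls:
                calls[(a, b)] = de_core.test_pair(filtered, design, a, b, **de_kwargs)
        de_counts = {
            f"{a}_vs_{b}": int((c["direction"] != "ns").sum())
            for (a, b), c in sorted(calls.items())
        }
        summary["deg_counts"] = de_counts
        tables["de_calls"] = pd.concat(calls.values(), ignore_index=True)

        # ---- stage: classify ---------------------------------------------
        stage = "classify"
        class_tables: dict[str, pd.DataFrame] = {}
        class_counts: dict[str, dict[str, int]] = {}
        for hybrid in design.hybrids:
            pa, pb = design.triad_parents(hybrid)
            assign = triad_classify.classify_calls(
                inheritance_sets.get_calls(calls, pa, pb),
                inheritance_sets.get_calls(calls, hybrid, pa),
                inheritance_sets.get_calls(calls, hybrid, pb),
            )
            assign.insert(1, "hybrid", hybrid)
            assign.insert(2, "parent_a", pa)
            assign.insert(3, "parent_b", pb)
            class_tables[hybrid] = assign
            class_counts[hybrid] = {
                str(k): int(v)
                for k, v in assign["subcategory"].value_counts().sort_index().items()
            }
        tables["classes"] = pd.concat(class_tables.values(), ignore_index=True)
        summary["class_counts"] = class_counts

        recg_tables = {}
        for name, hybrids in design.combinations.items():
            if len(hybrids) == 2:
                recg = triad_classify.reciprocal_consistent(
                    class_tables[hybrids[0]], class_tables[hybrids[1]]
                )
                recg.insert(1, "combination", name)
                recg_tables[name] = recg
        if recg_tables:
            tables["recgs"] = pd.concat(recg_tables.values(), ignore_index=True)
            summary["recg_counts"] = {
                name: int(len(t)) for name, t in sorted(recg_tables.items())
            }

        # ---- stage: sets --------------------------------------------------
        stage = "sets"
        ledger = inheritance_sets.build_deg_ledger(calls, design)
        dig_tables = {}
        maternal = {}
        for name, hybrids in design.combinations.items():
            if len(hybrids) != 2:
                continue
            h1, h2 = hybrids
            digs = inheritance_sets.detect_digs(calls, design, h1, h2)
            dig_tables[f"{h1}_{h2}"] = digs
            ledger.add(
                f"DIGs_{h1}_{h2}", digs["gene_id"], f"differential inheritance {h1}/{h2}"
            )
            if len(digs):
                attribution = inheritance_sets.maternal_attribution(digs, design)
                maternal[f"{h1}_{h2}"] = {
                    row["hybrid"]: (
                        None
                        if pd.isna(row["maternal_fraction"])
                        else round(float(row["maternal_fraction"]), 4)
                    )
                    for _, row in attribution.iterrows()
                }
        tables["set_membership"] = ledger.membership_frame()
        tables["set_overlaps"] = ledger.overlap_frame()
        summary["set_sizes"] = {k: len(v) for k, v in sorted(ledger.sets.items())}
        summary["maternal_attribution"] = maternal

        # ---- stage: heterosis --------------------------------------------
        if pheno is not None:
            stage = "heterosis"
            het = heterosis_metrics.heterosis_indices(pheno, design)
            tables["heterosis"] = het
            anova_rows = [
                heterosis_metrics.one_way_anova(pheno, t)
                for t in sorted(pheno["trait"].unique())
            ]
            tables["anova"] = pd.DataFrame(anova_rows)
            r, p = heterosis_metrics.trait_correlation(pheno)
            tables["trait_correlation"] = r.round(6).reset_index(names="trait")
            summary["heterosis"] = {
                f"{row['hybrid']}:{row['trait']}": {
                    "mph": round(float(row["mph"]), 4),
                    "bph": round(float(row["bph"]), 4),
                }
                for _, row in het.iterrows()
            }

        # ---- stage: enrichment + hubs ------------------------------------
        if term_map is not None:
            stage = "enrichment"
            background = list(filtered.gene_ids)
            enr_tables = []
            for name, recg in sorted(recg_tables.items()):
                study = recg.loc[recg["subcategory"] != 14, "gene_id"]
                study = [g for g in study if g in set(background)]
                if not study:
                    continue
                enr = enrichment_and_hubs.enrich_terms(
                    study, background, term_map,
                    padj_threshold=config.enrich_padj,
                    min_count=config.enrich_min_count,
                )
                enr.insert(0, "study_set", f"ReCGs_{name}")
                enr_tables.append(enr)
            if enr_tables:
                tables["enrichment"] = pd.concat(enr_tables, ignore_index=True)
                summary["enriched_terms"] = int(
                    tables["enrichment"]["pass"].sum()
                )

            stage = "hubs"
            combos = [c for c, hs in design.combinations.items() if len(hs) == 2]
            if len(combos) >= 2:
                pair_a = design.combinations[combos[0]]
                pair_b = design.combinations[combos[1]]
                hubs = enrichment_and_hubs.screen_hubs(
                    class_tables,
                    filtered.genotype_means(design),
                    term_map,
                    reciprocal_pair=pair_a,
                    other_pair=pair_b,
                    focal_terms=synthetic_data.FOCAL_TERMS,
                    pseudocount=config.pseudocount,
                )
                tables["hub_candidates"] = hubs
                summary["n_hub_candidates"] = int(hubs["gene_id"].nunique())

        # ---- stage: methylation ------------------------------------------
        if sites is not None and gene_models is not None:
            stage = "methylation"
            assignments = methylation_link.assign_regions(
                sites, gene_models, flank=config.flank
            )
            levels = methylation_link.region_level(
                sites, assignments, agg=config.meth_agg
            )
            corr = methylation_link.meth_expr_correlation(
                levels, filtered, design=design
            )
            tables["meth_region_levels"] = levels
            tables["meth_expr_correlation"] = corr
            summary["meth_expr_correlation"] = {
                f"{row['region']}:{row['context']}": round(float(row["r"]), 4)
                for _, row in corr.iterrows()
            }
            rpm = sites.rpm()
            dms_all = []
            for hybrid in design.hybrids:
                pa, pb = design.triad_parents(hybrid)
                dms = methylation_link.classify_dms(
                    site_rpm=rpm, parent_a=pa, parent_b=pb, hybrid=hybrid,
                    pseudocount=config.pseudocount,
                    lfc_threshold=config.lfc_threshold,
                )
                if "hybrid" not in dms.columns:
                    dms.insert(1, "hybrid", hybrid)
                dms_all.append(dms)
            dms_classes = pd.concat(dms_all, ignore_index=True)
            tables["dms_classes"] = dms_classes
            concordance = methylation_link.match_remodeling(
                tables["classes"], dms_classes, assignments
            )
            tables["concordance"] = concordance
            frac = {}
            for context, sub in concordance.groupby("context", sort=True):
                remod = sub[~sub["expr_subcategory"].isin([13, 14])]
                frac[context] = {
                    "consistent_pct": round(
                        100.0 * (sub["label"].isin(["consistent", "both"])).mean(), 3
                    ),
                    "conflicting_pct": round(
                        100.0 * (sub["label"].isin(["conflicting", "both"])).mean(), 3
                    ),
                    "remodeled_consistent_pct": round(
                        100.0 * (remod["label"].isin(["consistent", "both"])).mean(), 3
                    )
                    if len(remod)
                    else None,
                    "remodeled_conflicting_pct": round(
                        100.0 * (remod["label"].isin(["conflicting", "both"])).mean(), 3
                    )
                    if len(remod)
                    else None,
                    "n": int(len(sub)),
                    "n_remodeled": int(len(remod)),
                }
            summary["concordance"] = frac
            tables["meth_feature_distribution"] = (
                methylation_link.feature_distribution(dms_classes, assignments)
            )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    io_formats.write_results(tables, out_dir, command=command)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    bundle = {"summary": summary, "tables": tables, "out_dir": out_dir}
    if truth is not None:
        bundle["truth"] = truth
        bundle["truth_methylation"] = truth_m
        bundle["truth_phenotypes"] = truth_p
    return bundle
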