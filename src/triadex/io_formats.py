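"""Tabular I/O and validated in-memory containers for the triad pipeline.

Every table the pipeline touches is plain TSV.  Writers emit a provenance
header line ``#triadex <version> <command>``; readers skip ``#`` comment
lines.  Genomic coordinates are 1-based inclusive throughout.

The containers here are thin, validated wrappers around pandas objects:

``ExpressionMatrix``
    gene x sample FPKM grid, optionally carrying raw counts on the same
    grid and per-gene transcript lengths (bp).
``TriadDesign``
    genotype roles (parent/hybrid), hybrid parentage with maternal order,
    the sample -> (genotype, replicate) map, and the derived reciprocal
    crossing combinations.
``MethylationSiteTable``
    per-site, per-genotype relative methylation (RPM) restricted to the
    two assayed restriction-motif contexts, CCGG and CCWGG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__

VALID_CONTEXTS = ("CCGG", "CCWGG")
VALID_STRANDS = ("+", "-")
VALID_ROLES = ("parent", "hybrid")


class ValidationError(ValueError):
    """An input table violates a container invariant."""


class ParseError(ValueError):
    """An input cell could not be parsed; message names row and column."""


def provenance_line(command: str = "") -> str:
    return f"#triadex {__version__} {command}".rstrip()


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Non-negative gene x sample abundance (FPKM), with optional counts.

    Parameters
    ----------
    fpkm
        DataFrame indexed by unique gene ids, columns are unique sample ids.
    counts
        Optional raw counts aligned to the same gene x sample grid.
    gene_lengths
        Optional per-gene transcript length in bp (positive integers),
        indexed like ``fpkm``.
    """

    fpkm: pd.DataFrame
    counts: pd.DataFrame | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.fpkm.empty:
            raise ValidationError("expression matrix is empty")
        if not self.fpkm.index.is_unique:
            dupes = self.fpkm.index[self.fpkm.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene ids: {dupes[:5]}")
        if not self.fpkm.columns.is_unique:
            raise ValidationError("duplicated sample ids")
        values = self.fpkm.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if np.isnan(values).any():
            raise ValidationError("expression matrix contains missing values")
        if (values < 0).any():
            gene = self.fpkm.index[np.where(values < 0)[0][0]]
            raise ValidationError(f"negative expression value at gene {gene!r}")
        if self.counts is not None:
            if not (
                self.counts.index.equals(self.fpkm.index)
                and self.counts.columns.equals(self.fpkm.columns)
            ):
                raise ValidationError("counts do not align to the FPKM grid")
            if (self.counts.to_numpy() < 0).any():
                raise ValidationError("negative counts")
        if self.gene_lengths is not None:
            if not self.gene_lengths.index.equals(self.fpkm.index):
                raise ValidationError("gene_lengths do not align to gene ids")
            if (self.gene_lengths.to_numpy() <= 0).any():
                raise ValidationError("gene lengths must be positive")

    @property
    def gene_ids(self) -> pd.Index:
        return self.fpkm.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.fpkm.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            fpkm=self.fpkm.loc[genes],
            counts=None if self.counts is None else self.counts.loc[genes],
            gene_lengths=None
            if self.gene_lengths is None
            else self.gene_lengths.loc[genes],
        )

    def genotype_means(self, design: "TriadDesign") -> pd.DataFrame:
        """Replicate-mean FPKM per genotype (genes x genotypes)."""
        cols = {}
        for genotype in design.genotypes:
            cols[genotype] = self.fpkm[design.samples_of(genotype)].mean(axis=1)
        return pd.DataFrame(cols)


def _numeric_frame(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Coerce every cell to float, naming the first offending cell."""
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(
                f"{path}: malformed numeric cell at row {row!r}, column {col!r}: "
                f"{df[col][bad].iloc[0]!r}"
            )
        out[col] = converted
    return pd.DataFrame(out, index=df.index)


def read_expression(path, counts_path=None, lengths_path=None) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV (first column gene ids, header sample ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    if not raw.index.is_unique:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicated gene ids: {dupes[:5]}")
    fpkm = _numeric_frame(raw, str(path))
    if fpkm.isna().any().any():
        raise ValidationError(f"{path}: missing expression values")
    counts = None
    if counts_path is not None:
        counts = _numeric_frame(
            pd.read_csv(counts_path, sep="\t", comment="#", index_col=0, dtype=str),
            str(counts_path),
        )
        counts.index = counts.index.astype(str)
    lengths = None
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", comment="#", index_col=0)
        lengths = ldf.iloc[:, 0].astype(int)
        lengths.index = lengths.index.astype(str)
    return ExpressionMatrix(fpkm=fpkm, counts=counts, gene_lengths=lengths)


def write_expression(matrix: ExpressionMatrix, path, command: str = "") -> None:
    _write_tsv(matrix.fpkm.sort_index(), path, command, index_label="gene_id")


# ---------------------------------------------------------------------------
# Design


@dataclass(frozen=True)
class TriadDesign:
    """Genotype roles, hybrid parentage and the sample map for one study.

    ``parentage`` records the maternal parent first, mirroring the cross
    notation (F12 = P1 x P2 with P1 maternal).  Crossing combinations group
    reciprocal hybrids by their unordered parent pair; the *canonical*
    parent order of a combination is the sorted pair, shared by both
    reciprocal hybrids so that their triad classifications are directly
    comparable.
    """

    roles: Mapping[str, str]
    parentage: Mapping[str, tuple[str, str]]
    sample_map: Mapping[str, tuple[str, int]]

    def __post_init__(self) -> None:
        for genotype, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValidationError(f"genotype {genotype!r}: unknown role {role!r}")
        parents = {g for g, r in self.roles.items() if r == "parent"}
        for hybrid, (mat, pat) in self.parentage.items():
            if self.roles.get(hybrid) != "hybrid":
                raise ValidationError(f"{hybrid!r} has parentage but is not a hybrid")
            if mat == pat:
                raise ValidationError(f"hybrid {hybrid!r}: maternal == paternal ({mat!r})")
            for p in (mat, pat):
                if p not in parents:
                    raise ValidationError(
                        f"hybrid {hybrid!r} references undeclared parent {p!r}"
                    )
        hybrids = {g for g, r in self.roles.items() if r == "hybrid"}
        if missing := hybrids - set(self.parentage):
            raise ValidationError(f"hybrids without parentage: {sorted(missing)}")
        counts: dict[str, int] = {}
        for sample, (genotype, _rep) in self.sample_map.items():
            if genotype not in self.roles:
                raise ValidationError(
                    f"sample {sample!r} references undeclared genotype {genotype!r}"
                )
            counts[genotype] = counts.get(genotype, 0) + 1
        for genotype in self.roles:
            if counts.get(genotype, 0) < 2:
                raise ValidationError(
                    f"genotype {genotype!r} has {counts.get(genotype, 0)} replicate "
                    "sample(s); at least 2 required"
                )

    # -- accessors ----------------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.roles)

    @property
    def parents(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "parent")

    @property
    def hybrids(self) -> list[str]:
        return sorted(g for g, r in self.roles.items() if r == "hybrid")

    def samples_of(self, genotype: str) -> list[str]:
        pairs = sorted(
            (rep, s) for s, (g, rep) in self.sample_map.items() if g == genotype
        )
        return [s for _rep, s in pairs]

    def parents_of(self, hybrid: str) -> tuple[str, str]:
        """(maternal, paternal) parents of *hybrid*."""
        return tuple(self.parentage[hybrid])

    @property
    def combinations(self) -> dict[str, tuple[str, ...]]:
        """Crossing-combination name -> hybrids sharing that parent pair."""
        groups: dict[tuple[str, str], list[str]] = {}
        for hybrid in self.hybrids:
            pair = tuple(sorted(self.parentage[hybrid]))
            groups.setdefault(pair, []).append(hybrid)
        return {f"{a}x{b}": tuple(sorted(hs)) for (a, b), hs in sorted(groups.items())}

    def combination_of(self, hybrid: str) -> str:
        a, b = sorted(self.parentage[hybrid])
        return f"{a}x{b}"

    def combination_parents(self, name: str) -> tuple[str, str]:
        a, b = name.split("x", 1)
        return a, b

    def triad_parents(self, hybrid: str) -> tuple[str, str]:
        """Canonical (parent_a, parent_b) for classifying *hybrid*'s triad."""
        return tuple(sorted(self.parentage[hybrid]))

    def reciprocal_of(self, hybrid: str) -> str | None:
        mat, pat = self.parentage[hybrid]
        for other, (m, p) in self.parentage.items():
            if other != hybrid and (m, p) == (pat, mat):
                return other
        return None


def read_design(path) -> TriadDesign:
    """Read a design TSV with columns sample, genotype, role, maternal, paternal."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"sample", "genotype", "role", "maternal", "paternal"}
    if missing := required - set(df.columns):
        raise ValidationError(f"{path}: design is missing columns {sorted(missing)}")
    roles: dict[str, str] = {}
    parentage: dict[str, tuple[str, str]] = {}
    sample_map: dict[str, tuple[str, int]] = {}
    rep_counter: dict[str, int] = {}
    for _, row in df.iterrows():
        genotype = row["genotype"]
        prior = roles.get(genotype)
        if prior is not None and prior != row["role"]:
            raise ValidationError(
                f"{path}: genotype {genotype!r} declared with conflicting roles"
            )
        roles[genotype] = row["role"]
        if row["role"] == "hybrid":
            pair = (row["maternal"], row["paternal"])
            if genotype in parentage and parentage[genotype] != pair:
                raise ValidationError(
                    f"{path}: hybrid {genotype!r} has conflicting parentage"
                )
            parentage[genotype] = pair
        rep_counter[genotype] = rep_counter.get(genotype, 0) + 1
        if row["sample"] in sample_map:
            raise ValidationError(f"{path}: duplicated sample id {row['sample']!r}")
        sample_map[row["sample"]] = (genotype, rep_counter[genotype])
    return TriadDesign(roles=roles, parentage=parentage, sample_map=sample_map)


def design_frame(design: TriadDesign) -> pd.DataFrame:
    rows = []
    for sample, (genotype, rep) in sorted(
        design.sample_map.items(), key=lambda kv: (kv[1][0], kv[1][1])
    ):
        mat, pat = ("", "")
        if design.roles[genotype] == "hybrid":
            mat, pat = design.parentage[genotype]
        rows.append(
            {
                "sample": sample,
                "genotype": genotype,
                "role": design.roles[genotype],
                "maternal": mat,
                "paternal": pat,
            }
        )
    return pd.DataFrame(rows)


def write_design(design: TriadDesign, path, command: str = "") -> None:
    _write_tsv(design_frame(design), path, command, index=False)


# ---------------------------------------------------------------------------
# Gene models


def validate_gene_models(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene-model table (gene_id, chrom, start, end, strand)."""
    required = ["gene_id", "chrom", "start", "end", "strand"]
    if missing := set(required) - set(df.columns):
        raise ValidationError(f"gene models missing columns {sorted(missing)}")
    df = df[required].copy()
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicated gene ids in gene models")
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene_id"].iloc[0]
        raise ValidationError(f"gene {bad!r}: start > end")
    if (df["start"] < 1).any():
        raise ValidationError("gene model coordinates are 1-based; start < 1")
    if (~df["strand"].isin(VALID_STRANDS)).any():
        bad = df.loc[~df["strand"].isin(VALID_STRANDS), "strand"].iloc[0]
        raise ValidationError(f"invalid strand {bad!r}")
    return df


def read_gene_models(path) -> pd.DataFrame:
    """Read a BED/GFF-lite TSV: chrom, start, end, strand, gene_id (1-based)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=["chrom", "start", "end", "strand", "gene_id"],
        dtype={"chrom": str, "strand": str, "gene_id": str},
    )
    return validate_gene_models(df)


def write_gene_models(genes: pd.DataFrame, path, command: str = "") -> None:
    genes = validate_gene_models(genes)
    out = genes[["chrom", "start", "end", "strand", "gene_id"]].sort_values(
        ["chrom", "start", "gene_id"], kind="stable"
    )
    with open(path, "w") as fh:
        fh.write(provenance_line(command) + "\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Methylation sites


@dataclass
class MethylationSiteTable:
    """Per-site, per-genotype RPM for the CCGG / CCWGG contexts.

    ``sites`` carries columns site_id, chrom, pos, context plus one RPM
    column per genotype (listed in ``genotypes``; column order defines
    genotype order).
    """

    sites: pd.DataFrame
    genotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        required = {"site_id", "chrom", "pos", "context"}
        if missing := required - set(self.sites.columns):
            raise ValidationError(f"site table missing columns {sorted(missing)}")
        if missing := set(self.genotypes) - set(self.sites.columns):
            raise ValidationError(f"site table missing RPM columns {sorted(missing)}")
        bad = ~self.sites["context"].isin(VALID_CONTEXTS)
        if bad.any():
            raise ValidationError(
                f"unknown methylation context {self.sites.loc[bad, 'context'].iloc[0]!r}; "
                f"expected one of {VALID_CONTEXTS}"
            )
        if self.sites["site_id"].duplicated().any():
            raise ValidationError("duplicated site ids")
        rpm = self.sites[list(self.genotypes)].to_numpy()
        if (rpm < 0).any():
            raise ValidationError("negative RPM value")

    def rpm(self) -> pd.DataFrame:
        return self.sites.set_index("site_id")[list(self.genotypes)]


def read_methylation_sites(path) -> MethylationSiteTable:
    """Read a BED-like TSV: chrom, pos (1-based), context, then RPM per genotype."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("chrom", "pos", "context"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    genotypes = tuple(c for c in df.columns if c not in ("chrom", "pos", "context"))
    if not genotypes:
        raise ValidationError(f"{path}: no genotype RPM columns")
    df["pos"] = df["pos"].astype(int)
    rpm = _numeric_frame(df[list(genotypes)], str(path))
    if rpm.isna().any().any():
        warnings.warn(f"{path}: missing RPM values treated as 0", stacklevel=2)
        rpm = rpm.fillna(0.0)
    out = df[["chrom", "pos", "context"]].copy()
    out[list(genotypes)] = rpm
    out.insert(0, "site_id", out["chrom"] + ":" + out["pos"].astype(str) + ":" + out["context"])
    return MethylationSiteTable(sites=out, genotypes=genotypes)


def write_methylation_sites(table: MethylationSiteTable, path, command: str = "") -> None:
    cols = ["chrom", "pos", "context", *table.genotypes]
    out = table.sites[cols].sort_values(["chrom", "pos", "context"], kind="stable")
    _write_tsv(out, path, command, index=False)


# ---------------------------------------------------------------------------
# Phenotypes


def validate_phenotypes(df: pd.DataFrame, min_replicates: int = 3) -> pd.DataFrame:
    required = ["genotype", "trait", "replicate", "value"]
    if missing := set(required) - set(df.columns):
        raise ValidationError(f"phenotype table missing columns {sorted(missing)}")
    df = df[required].copy()
    df["value"] = df["value"].astype(float)
    counts = df.groupby(["genotype", "trait"]).size()
    if (counts < min_replicates).any():
        genotype, trait = counts.idxmin()
        raise ValidationError(
            f"genotype {genotype!r} trait {trait!r} has {counts.min()} replicates; "
            f"at least {min_replicates} required"
        )
    return df


def read_phenotypes(path, min_replicates: int = 3) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return validate_phenotypes(df, min_replicates=min_replicates)


# ---------------------------------------------------------------------------
# Generic results


def _write_tsv(df: pd.DataFrame, path, command: str = "", index=True, index_label=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(command) + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def write_table(df: pd.DataFrame, path, command: str = "") -> None:
    """Write a result table: deterministic column order, stable sort on the
    first column, provenance header, TSV."""
    if df.empty:
        out = df
    else:
        out = df.sort_values(df.columns[0], kind="stable")
    _write_tsv(out, path, command, index=False)


def read_table(path) -> pd.DataFrame:
    # round_trip parsing so write/read is the identity on float64 values
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, command: str = "") -> list[Path]:
    """Write every named table as ``<name>.tsv`` under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in sorted(tables):
        path = out_dir / f"{name}.tsv"
        write_table(tables[name], path, command=command)
        written.append(path)
    return written
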