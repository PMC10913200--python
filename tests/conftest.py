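"""Shared fixtures: small synthetic datasets and toy table builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from triadex import synthetic_data as sd
from triadex.io_formats import ExpressionMatrix, TriadDesign


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated study (600 genes, seed 7) shared across tests."""
    config = sd.SimulationConfig(n_genes=600, seed=7)
    matrix, design, truth = sd.generate_triad_dataset(config)
    return config, matrix, design, truth


@pytest.fixture(scope="session")
def two_group_design() -> TriadDesign:
    """Minimal two-parent design (3 replicates each) for pairwise tests."""
    return TriadDesign(
        roles={"A": "parent", "B": "parent"},
        parentage={},
        sample_map={
            f"{g}_r{i}": (g, i) for g in ("A", "B") for i in (1, 2, 3)
        },
    )


def make_matrix(values: dict[str, list[float]], genes=None) -> ExpressionMatrix:
    """Expression matrix from sample -> per-gene value lists."""
    df = pd.DataFrame(values)
    df.index = pd.Index(
        genes if genes is not None else [f"g{i + 1}" for i in range(len(df))],
        name="gene_id",
    )
    return ExpressionMatrix(fpkm=df.astype(float))


@pytest.fixture
def triad_design() -> TriadDesign:
    """Two parents plus one reciprocal hybrid pair, 3 replicates each."""
    roles = {"P1": "parent", "P2": "parent", "F12": "hybrid", "F21": "hybrid"}
    parentage = {"F12": ("P1", "P2"), "F21": ("P2", "P1")}
    sample_map = {
        f"{g}_r{i}": (g, i) for g in roles for i in (1, 2, 3)
    }
    return TriadDesign(roles=roles, parentage=parentage, sample_map=sample_map)


def replicate_matrix(
    means: pd.DataFrame, design: TriadDesign, noise_sd: float = 0.0, seed: int = 0
) -> ExpressionMatrix:
    """Expand a genes x genotypes mean table into per-replicate columns."""
    rng = np.random.default_rng(seed)
    cols = {}
    for genotype in design.genotypes:
        for sample in design.samples_of(genotype):
            jitter = rng.normal(0, noise_sd, size=len(means)) if noise_sd else 0.0
            cols[sample] = np.maximum(means[genotype].to_numpy() + jitter, 0.0)
    return ExpressionMatrix(fpkm=pd.DataFrame(cols, index=means.index))
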