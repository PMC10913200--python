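"""Expression filtering and pairwise differential-expression calling.

A gene is differentially expressed between two genotypes when the raw
p-value is below ``p_threshold`` (default 0.05) *and* the absolute log2
fold change strictly exceeds ``lfc_threshold`` (default 1).  Fold changes
are computed on replicate-mean FPKM with a pseudocount so that zeros never
divide; the default test is a two-sided Welch t on log2(FPKM + pseudocount),
with an optional moment-based negative-binomial Wald test on raw counts.

Degenerate rows (zero within-group variance in both groups) fall back to
p = 1 when the group means are equal, and otherwise to an exact two-group
permutation test over replicate labels, which avoids manufacturing
spurious certainty from constant data.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, TriadDesign, ValidationError

DE_METHODS = ("welch_log", "nb_wald")


def filter_low_expression(
    matrix: ExpressionMatrix, design: TriadDesign, threshold: float = 1.0
) -> ExpressionMatrix:
    """Discard genes whose replicate-mean FPKM is below *threshold* in
    every genotype; a gene is retained as soon as one genotype's mean
    reaches the threshold."""
    means = matrix.genotype_means(design)
    keep = (means >= threshold).any(axis=1)
    if not keep.any():
        raise ValidationError("no genes survive the low-expression filter")
    return matrix.subset_genes(matrix.gene_ids[keep])


def _perm_p(a: np.ndarray, b: np.ndarray) -> float:
    """Exact permutation p for |mean(a) - mean(b)| over replicate labels."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    observed = abs(a.mean() - b.mean())
    total = sum(1 for _ in combinations(range(n), na))
    hits = 0
    for idx in combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        if abs(pooled[mask].mean() - pooled[~mask].mean()) >= observed - 1e-12:
            hits += 1
    return hits / total


def _directions(
    log2fc: np.ndarray, p: np.ndarray, p_threshold: float, lfc_threshold: float
) -> np.ndarray:
    sig = (p < p_threshold) & (np.abs(log2fc) > lfc_threshold)
    out = np.full(log2fc.shape, "ns", dtype=object)
    out[sig & (log2fc > 0)] = "up"
    out[sig & (log2fc < 0)] = "down"
    return out


def _welch_log_p(a: np.ndarray, b: np.ndarray, pseudocount: float) -> np.ndarray:
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision warning; those rows are
        # re-handled by the degenerate fallback below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.asarray(p)
    # zero within-group spread in both groups: the t statistic is
    # meaningless (NaN, infinite, or dominated by rounding error), so fall
    # back to the degenerate rules; constancy is judged by range, which is
    # exact where a float variance of identical values may not be
    constant_a = np.ptp(la, axis=1) == 0
    constant_b = np.ptp(lb, axis=1) == 0
    degenerate = np.isnan(p) | (constant_a & constant_b)
    for i in np.where(degenerate)[0]:
        if np.isclose(la[i].mean(), lb[i].mean()):
            p[i] = 1.0
        else:
            p[i] = _perm_p(la[i], lb[i])
    return np.asarray(p, dtype=float)


def _nb_wald_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Approximate NB Wald test on counts: method-of-moments dispersion,
    delta-method SE on the log-mean difference."""

    def log_mean_se(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        m_safe = np.maximum(m, 0.5)
        v = np.maximum(v, m_safe)  # floor at Poisson variance
        se = np.sqrt(v / x.shape[1]) / m_safe
        return np.log(m_safe), se

    la, sa = log_mean_se(a)
    lb, sb = log_mean_se(b)
    z = (la - lb) / np.sqrt(sa**2 + sb**2)
    p = 2 * stats.norm.sf(np.abs(z))
    both_const = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal = both_const & (a.mean(axis=1) == b.mean(axis=1))
    p[equal] = 1.0
    for i in np.where(both_const & ~equal)[0]:
        p[i] = _perm_p(a[i].astype(float), b[i].astype(float))
    return p


def test_pair(
    matrix: ExpressionMatrix,
    design: TriadDesign,
    group_a: str,
    group_b: str,
    method: str = "welch_log",
    pseudocount: float = 1.0,
    p_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE call between two genotypes.

    Returns a DataFrame with columns gene_id, group_a, group_b, log2fc,
    p_value, direction; log2fc = log2((mean_a + pc) / (mean_b + pc)) on
    replicate-mean FPKM, so swapping the groups negates log2fc and leaves
    p unchanged.
    """
    if method not in DE_METHODS:
        raise ValueError(f"unknown DE method {method!r}; expected one of {DE_METHODS}")
    samples_a = design.samples_of(group_a)
    samples_b = design.samples_of(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("both groups need at least 2 replicates")
    a = matrix.fpkm[samples_a].to_numpy(dtype=float)
    b = matrix.fpkm[samples_b].to_numpy(dtype=float)
    log2fc = np.log2((a.mean(axis=1) + pseudocount) / (b.mean(axis=1) + pseudocount))
    if method == "welch_log":
        p = _welch_log_p(a, b, pseudocount)
    else:
        if matrix.counts is None:
            raise ValidationError("method 'nb_wald' requires raw counts")
        p = _nb_wald_p(
            matrix.counts[samples_a].to_numpy(dtype=float),
            matrix.counts[samples_b].to_numpy(dtype=float),
        )
    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "group_a": group_a,
            "group_b": group_b,
            "log2fc": log2fc,
            "p_value": p,
            "direction": _directions(log2fc, p, p_threshold, lfc_threshold),
        }
    ).reset_index(drop=True)


def calls_from_means(
    mean_a: pd.Series,
    mean_b: pd.Series,
    group_a: str = "A",
    group_b: str = "B",
    pseudocount: float = 1.0,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Threshold-only DE calls from genotype means (no replicates).

    Used for noise-free mean matrices and for genotype-level methylation
    RPM, where no within-group variance exists: the direction is up/down
    when |log2fc| strictly exceeds the threshold, else ns, with p set to 0
    or 1 accordingly.
    """
    log2fc = np.log2((mean_a.to_numpy(dtype=float) + pseudocount) /
                     (mean_b.to_numpy(dtype=float) + pseudocount))
    sig = np.abs(log2fc) > lfc_threshold
    direction = np.full(log2fc.shape, "ns", dtype=object)
    direction[sig & (log2fc > 0)] = "up"
    direction[sig & (log2fc < 0)] = "down"
    return pd.DataFrame(
        {
            "gene_id": mean_a.index,
            "group_a": group_a,
            "group_b": group_b,
            "log2fc": log2fc,
            "p_value": np.where(sig, 0.0, 1.0),
            "direction": direction,
        }
    ).reset_index(drop=True)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
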