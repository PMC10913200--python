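"""Heterosis indices, one-way ANOVA across genotypes, trait correlations.

Mid-parent heterosis and better-parent heterosis are percent deviations of
the hybrid genotype mean from, respectively, the parental average and the
optimal parent:

    MPH = 100 * (F1_mean - midparent_mean) / midparent_mean
    BPH = 100 * (F1_mean - best_parent_mean) / best_parent_mean

"Optimal parent" defaults to the parent with the larger mean; traits where
smaller is better can flip this per trait.  Both indices are computed on
genotype means over replicates and are invariant under rescaling the trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TriadDesign, ValidationError


def heterosis_indices(
    pheno: pd.DataFrame,
    design: TriadDesign,
    trait_direction: dict[str, str] | None = None,
) -> pd.DataFrame:
    """MPH and BPH per hybrid x trait.

    ``trait_direction`` maps trait -> 'larger' (default) or 'smaller',
    selecting which parent is optimal.  Rows with a zero mid-parent mean
    are flagged (mph NaN, defined=False) rather than dropped.
    """
    trait_direction = trait_direction or {}
    means = pheno.groupby(["genotype", "trait"])["value"].mean()
    rows = []
    for hybrid in design.hybrids:
        mat, pat = design.parents_of(hybrid)
        for trait in sorted(pheno["trait"].unique()):
            try:
                hybrid_mean = means[(hybrid, trait)]
                mat_mean = means[(mat, trait)]
                pat_mean = means[(pat, trait)]
            except KeyError:
                continue  # hybrid or a parent unmeasured for this trait
            mid = 0.5 * (mat_mean + pat_mean)
            if trait_direction.get(trait, "larger") == "smaller":
                best = min(mat_mean, pat_mean)
            else:
                best = max(mat_mean, pat_mean)
            defined = mid != 0 and best != 0
            rows.append(
                {
                    "hybrid": hybrid,
                    "trait": trait,
                    "maternal_mean": mat_mean,
                    "paternal_mean": pat_mean,
                    "hybrid_mean": hybrid_mean,
                    "mid_parent": mid,
                    "best_parent": best,
                    "mph": 100.0 * (hybrid_mean - mid) / mid if defined else np.nan,
                    "bph": 100.0 * (hybrid_mean - best) / best if defined else np.nan,
                    "defined": defined,
                }
            )
    return pd.DataFrame(rows)


def one_way_anova(pheno: pd.DataFrame, trait: str) -> dict:
    """Classical one-way F test of genotype effect on *trait*.

    Degenerate inputs: all groups constant with equal means -> F=0, p=1;
    constant groups with unequal means -> p=0 flagged degenerate.
    """
    sub = pheno[pheno["trait"] == trait]
    groups = [g["value"].to_numpy(dtype=float) for _, g in sub.groupby("genotype")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >=2 genotypes with >=2 replicates each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    within_var = sum(g.var(ddof=1) for g in groups)
    result = {"trait": trait, "n_groups": k, "df_between": k - 1, "df_within": n - k,
              "degenerate": False}
    if within_var == 0:
        means = [g.mean() for g in groups]
        if len(set(means)) == 1:
            result.update(F=0.0, p_value=1.0)
        else:
            result.update(F=np.inf, p_value=0.0, degenerate=True)
        return result
    f, p = stats.f_oneway(*groups)
    result.update(F=float(f), p_value=float(p))
    return result


def trait_correlation(
    pheno: pd.DataFrame, on: str = "genotype_mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix between traits, with two-sided p-values.

    ``on='genotype_mean'`` (default) correlates genotype means across
    genotypes; ``on='replicate'`` pools replicate observations.  Zero
    variance traits yield NaN entries (flagged undefined) off-diagonal.
    """
    if on == "genotype_mean":
        wide = pheno.groupby(["genotype", "trait"])["value"].mean().unstack("trait")
    elif on == "replicate":
        wide = pheno.pivot_table(
            index=["genotype", "replicate"], columns="trait", values="value"
        )
    else:
        raise ValueError(f"unknown correlation mode {on!r}")
    if len(wide) < 3:
        raise ValidationError("trait correlation needs >=3 paired observations")
    traits = list(wide.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, ti in enumerate(traits):
        for j in range(i + 1, len(traits)):
            tj = traits[j]
            x, y = wide[ti].to_numpy(), wide[tj].to_numpy()
            if x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r.loc[ti, tj] = r.loc[tj, ti] = rij
            p.loc[ti, tj] = p.loc[tj, ti] = pij
    return r, p
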