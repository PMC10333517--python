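"""Cross-species divergence of response variability.

The slope of the per-gene mean-variance line indexes response
heterogeneity; evolutionary changes in heterogeneity are measured by
comparing slopes between species.  Two slopes are compared with a
Student's t-test,

    t = (alpha1 - alpha2) / sqrt(SE1^2 + SE2^2),  d.o.f. = n1 + n2 - 4,

with BH-FDR correction across comparisons.  The slope ratio
k = max(alpha1, alpha2) / min(alpha1, alpha2) quantifies the magnitude
of divergence; genes with k > 2 in a species pair are stratified as
divergent towards the higher-slope species.  Under a zero intercept a
fold-change k in the slope predicts burst size scaled by k and burst
frequency by 1/k at matched expression.

Response divergence (against the outgroup species) is
log[(1/3) sum_j (log FC_out - log FC_j)^2] over the three ingroup
species, natural logs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mean_variance import MeanVarianceFit, bh_fdr

__all__ = [
    "SlopeComparison",
    "slope_ttest",
    "pairwise_species",
    "stratify_divergence",
    "response_divergence",
    "complexity_slope_correlation",
    "DIVERGENCE_FOLD",
]

DIVERGENCE_FOLD = 2.0


@dataclass
class SlopeComparison:
    """t-test of the mean-variance slopes of one gene in two species."""

    gene_id: str
    species_a: str
    species_b: str
    alpha_a: float
    alpha_b: float
    t: float
    dof: int
    p: float
    k: float
    q: float = np.nan

    @property
    def divergent(self) -> bool:
        return self.k > DIVERGENCE_FOLD


def slope_ttest(
    fit1: MeanVarianceFit,
    fit2: MeanVarianceFit,
    species: tuple[str, str] = ("A", "B"),
) -> SlopeComparison:
    """Student's t-test for a slope difference between two robust fits."""

    if fit1.failed or fit2.failed:
        raise ValueError("both fits must be valid")
    if not (fit1.se_alpha > 0 and fit2.se_alpha > 0):
        raise ValueError("slope standard errors must be > 0")
    dof = fit1.n_conditions + fit2.n_conditions - 4
    if dof <= 0:
        raise ValueError("n1 + n2 must exceed 4")
    t = (fit1.alpha - fit2.alpha) / np.hypot(fit1.se_alpha, fit2.se_alpha)
    p = 2.0 * stats.t.sf(abs(t), dof)
    a1, a2 = fit1.alpha, fit2.alpha
    k = max(a1, a2) / min(a1, a2) if min(a1, a2) > 0 else np.inf
    return SlopeComparison(
        gene_id=fit1.gene_id,
        species_a=species[0],
        species_b=species[1],
        alpha_a=a1,
        alpha_b=a2,
        t=float(t),
        dof=dof,
        p=float(p),
        k=float(k),
    )


def pairwise_species(
    fits: dict[str, dict[str, MeanVarianceFit]],
    fdr_scope: str = "global",
) -> tuple[list[SlopeComparison], pd.Series]:
    """All pairwise slope tests across species, per gene, with BH-FDR.

    ``fits`` maps species -> gene -> fit.  With four species each gene
    yields six comparisons.  ``fdr_scope`` is "global" (one family over
    all genes x pairs, the default) or "per_gene".  Returns the
    comparisons and the per-gene count of significant (q < 0.05) pairs.
    """

    species = sorted(fits)
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    genes = sorted(set.intersection(*(set(fits[s]) for s in species)))
    comparisons: list[SlopeComparison] = []
    for gene in genes:
        for sa, sb in itertools.combinations(species, 2):
            fa, fb = fits[sa][gene], fits[sb][gene]
            if fa.failed or fb.failed:
                continue
            comparisons.append(slope_ttest(fa, fb, species=(sa, sb)))
    if fdr_scope == "global":
        qs = bh_fdr([c.p for c in comparisons])
        for c, q in zip(comparisons, qs):
            c.q = float(q)
    elif fdr_scope == "per_gene":
        for gene in genes:
            sub = [c for c in comparisons if c.gene_id == gene]
            qs = bh_fdr([c.p for c in sub])
            for c, q in zip(sub, qs):
                c.q = float(q)
    else:
        raise ValueError("fdr_scope must be 'global' or 'per_gene'")
    counts = pd.Series(
        {
            gene: sum(c.q < 0.05 for c in comparisons if c.gene_id == gene)
            for gene in genes
        },
        name="n_significant_pairs",
    )
    return comparisons, counts


def stratify_divergence(
    comparisons: list[SlopeComparison],
    species_pair: tuple[str, str],
    fold: float = DIVERGENCE_FOLD,
) -> pd.Series:
    """Per-gene divergence class for one species pair.

    ``divergent_A`` when alpha_A > fold * alpha_B, ``divergent_B`` when
    alpha_B > fold * alpha_A, else ``non_divergent``.
    """

    sa, sb = species_pair
    out = {}
    for c in comparisons:
        if {c.species_a, c.species_b} != {sa, sb}:
            continue
        a_a = c.alpha_a if c.species_a == sa else c.alpha_b
        a_b = c.alpha_b if c.species_b == sb else c.alpha_a
        if a_a > fold * a_b:
            out[c.gene_id] = f"divergent_{sa}"
        elif a_b > fold * a_a:
            out[c.gene_id] = f"divergent_{sb}"
        else:
            out[c.gene_id] = "non_divergent"
    return pd.Series(out, name="divergence_class")


def response_divergence(
    fc_outgroup: float, fc_ingroup: list[float] | np.ndarray
) -> float:
    """log of the mean squared log fold-change difference vs the outgroup.

    Natural logs.  Undefined (raises) for non-positive fold changes or
    identical responses (the inner sum is zero).
    """

    fcs = np.asarray(fc_ingroup, dtype=float)
    if fc_outgroup <= 0 or (fcs <= 0).any():
        raise ValueError("all fold changes must be > 0")
    inner = np.mean((np.log(fc_outgroup) - np.log(fcs)) ** 2)
    if inner == 0:
        raise ValueError("identical log fold changes: divergence undefined")
    return float(np.log(inner))


def complexity_slope_correlation(
    slope_ratios: np.ndarray | list[float],
    complexity_ratios: np.ndarray | list[float],
) -> tuple[float, float]:
    """Spearman correlation between slope ratios and 3-state-win ratios.

    Each point is one gene x species-pair: the ratio of mean-variance
    slopes alpha_A / alpha_B against the ratio of the species' numbers
    of conditions best fitted by the 3-state model.  Returns (r, p) with
    a one-sided p-value for r > 0; ties are handled by average ranks.
    """

    x = np.asarray(slope_ratios, dtype=float)
    y = np.asarray(complexity_ratios, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need >= 5 paired ratios")
    res = stats.spearmanr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def comparisons_to_frame(comparisons: list[SlopeComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in comparisons],
            "species_a": [c.species_a for c in comparisons],
            "species_b": [c.species_b for c in comparisons],
            "alpha_a": [c.alpha_a for c in comparisons],
            "alpha_b": [c.alpha_b for c in comparisons],
            "t": [c.t for c in comparisons],
            "dof": [c.dof for c in comparisons],
            "p": [c.p for c in comparisons],
            "q": [c.q for c in comparisons],
            "k": [c.k for c in comparisons],
            "divergent": [c.divergent for c in comparisons],
        }
    )
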