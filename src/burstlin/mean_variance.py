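"""Per-gene linear mean-variance fits across stimulation conditions.

For each gene, the sample mean mu and unbiased sample variance sigma^2
of its (median-scaled) counts are computed per condition, and the line
sigma^2 = alpha * mu + alpha0 is fitted across conditions by robust
linear regression (Huber M-estimator, tuning constant 1.345).  The
slope alpha indexes the gene's response heterogeneity.  A fit is
*high-confidence* when the FDR-adjusted slope p-value is below 0.05 and
the unweighted R^2 exceeds 0.6; genes passing only the significance
filter are *significant_only*, the rest *failed*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .dataio import ConditionKey, NormalizedDataset

__all__ = [
    "ConditionMoments",
    "MeanVarianceFit",
    "compute_moments",
    "fit_huber_line",
    "bh_fdr",
    "call_confidence",
    "fit_gene_panel",
    "HUBER_TUNING",
    "FDR_THRESHOLD",
    "R2_THRESHOLD",
]

HUBER_TUNING = 1.345
FDR_THRESHOLD = 0.05
R2_THRESHOLD = 0.6


@dataclass(frozen=True)
class ConditionMoments:
    """Sample moments of one gene's counts in one condition."""

    gene_id: str
    condition: ConditionKey
    mu: float
    var: float
    n: int


@dataclass
class MeanVarianceFit:
    """Robust line sigma^2 = alpha * mu + alpha0 for one gene."""

    gene_id: str
    alpha: float
    alpha0: float
    se_alpha: float
    se_alpha0: float
    p_alpha: float
    p_alpha0: float
    r2: float
    n_conditions: int
    failed: bool = False
    q_alpha: float = np.nan
    q_alpha0: float = np.nan
    confidence_class: str = "unassessed"
    moments: list[ConditionMoments] = field(default_factory=list, repr=False)

    def slope_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Slope confidence interval, t quantiles with n-2 d.o.f.

        The width uses a heteroskedasticity-consistent (HC3 sandwich)
        standard error recomputed from the fit's residuals when the
        condition moments are attached: the noise on a sample variance
        scales with sigma^2 and is right-skewed, which the model-based
        robust SE understates.  Falls back to ``se_alpha`` otherwise.
        """
        se = self._hc3_slope_se()
        tq = stats.t.ppf(0.5 + level / 2, self.n_conditions - 2)
        return self.alpha - tq * se, self.alpha + tq * se

    def _hc3_slope_se(self) -> float:
        if not self.moments or np.isnan(self.alpha):
            return self.se_alpha
        mu = np.array([m.mu for m in self.moments])
        var = np.array([m.var for m in self.moments])
        X = np.column_stack([np.ones_like(mu), mu])
        resid = var - (self.alpha0 + self.alpha * mu)
        xtx_inv = np.linalg.inv(X.T @ X)
        h = np.einsum("ij,jk,ik->i", X, xtx_inv, X)
        meat = X.T @ (X * (resid / (1.0 - h))[:, None] ** 2)
        cov = xtx_inv @ meat @ xtx_inv
        return float(np.sqrt(cov[1, 1]))


def compute_moments(
    nds: NormalizedDataset, view: str = "scaled"
) -> list[ConditionMoments]:
    """Per-(gene, condition) sample mean and unbiased (n-1) variance.

    Conditions with fewer than two cells are excluded with a warning
    (the variance is undefined there).
    """

    mat = nds.scaled if view == "scaled" else nds.integer_view
    out: list[ConditionMoments] = []
    for cond, idx in nds.conditions.items():
        if len(idx) < 2:
            warnings.warn(
                f"condition {cond} has {len(idx)} cell(s); excluded from moments",
                stacklevel=2,
            )
            continue
        sub = mat[:, idx]
        mus = sub.mean(axis=1)
        vars_ = sub.var(axis=1, ddof=1)
        for gi, gene in enumerate(nds.gene_ids):
            out.append(
                ConditionMoments(
                    gene_id=gene,
                    condition=cond,
                    mu=float(mus[gi]),
                    var=float(vars_[gi]),
                    n=len(idx),
                )
            )
    return out


def _failed_fit(gene_id: str, n: int, moments: list[ConditionMoments]) -> MeanVarianceFit:
    return MeanVarianceFit(
        gene_id=gene_id,
        alpha=np.nan,
        alpha0=np.nan,
        se_alpha=np.nan,
        se_alpha0=np.nan,
        p_alpha=np.nan,
        p_alpha0=np.nan,
        r2=np.nan,
        n_conditions=n,
        failed=True,
        moments=moments,
    )


def fit_huber_line(points: list[ConditionMoments]) -> MeanVarianceFit:
    """Robust regression of sigma^2 on mu across conditions.

    IRLS with the Huber norm (tuning constant 1.345) and MAD residual
    scale; standard errors come from the robust covariance of the fit.
    R^2 is computed unweighted over all points against the fitted line,
    including any robust-downweighted ones.
    """

    if len(points) < 3:
        raise ValueError("need at least 3 conditions to fit a line")
    gene_id = points[0].gene_id
    mu = np.array([p.mu for p in points])
    var = np.array([p.var for p in points])
    if np.ptp(mu) == 0:
        return _failed_fit(gene_id, len(points), list(points))
    X = sm.add_constant(mu)
    try:
        res = sm.RLM(var, X, M=sm.robust.norms.HuberT(t=HUBER_TUNING)).fit(
            conv="coefs", tol=1e-8, maxiter=200
        )
    except (np.linalg.LinAlgError, ValueError):
        return _failed_fit(gene_id, len(points), list(points))
    alpha0, alpha = res.params
    se_alpha0, se_alpha = res.bse
    p_alpha0, p_alpha = res.pvalues
    fitted = alpha0 + alpha * mu
    ss_res = float(np.sum((var - fitted) ** 2))
    ss_tot = float(np.sum((var - var.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else np.nan)
    return MeanVarianceFit(
        gene_id=gene_id,
        alpha=float(alpha),
        alpha0=float(alpha0),
        se_alpha=float(se_alpha),
        se_alpha0=float(se_alpha0),
        p_alpha=float(p_alpha),
        p_alpha0=float(p_alpha0),
        r2=r2,
        n_conditions=len(points),
        moments=list(points),
    )


def bh_fdr(pvals: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving.

    NaN p-values propagate as NaN and are excluded from the ranking.
    """

    p = np.asarray(pvals, dtype=float)
    q = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if pm.size:
        if (pm < 0).any() or (pm > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        m = pm.size
        order = np.argsort(pm, kind="mergesort")
        ranked = pm[order] * m / np.arange(1, m + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(m)
        adj[order] = np.minimum(ranked, 1.0)
        q[mask] = adj
    return q


def call_confidence(fits: list[MeanVarianceFit]) -> list[MeanVarianceFit]:
    """Apply BH-FDR across the fitted genes and assign confidence classes.

    high_confidence: q_alpha < 0.05 and R^2 > 0.6;
    significant_only: q_alpha < 0.05 and R^2 <= 0.6; else failed.
    The FDR family is the full set of genes fitted in one run.
    """

    qa = bh_fdr([f.p_alpha for f in fits])
    qa0 = bh_fdr([f.p_alpha0 for f in fits])
    for f, q, q0 in zip(fits, qa, qa0):
        f.q_alpha = float(q)
        f.q_alpha0 = float(q0)
        if f.failed or np.isnan(f.q_alpha):
            f.confidence_class = "failed"
        elif f.q_alpha < FDR_THRESHOLD and f.r2 > R2_THRESHOLD:
            f.confidence_class = "high_confidence"
        elif f.q_alpha < FDR_THRESHOLD:
            f.confidence_class = "significant_only"
        else:
            f.confidence_class = "failed"
    return fits


def fit_gene_panel(
    nds: NormalizedDataset, view: str = "scaled"
) -> list[MeanVarianceFit]:
    """Moments, robust fits and confidence calls for every gene in a dataset."""

    moments = compute_moments(nds, view=view)
    by_gene: dict[str, list[ConditionMoments]] = {}
    for m in moments:
        by_gene.setdefault(m.gene_id, []).append(m)
    fits = []
    for gene in nds.gene_ids:
        pts = by_gene.get(gene, [])
        if len(pts) < 3:
            fits.append(_failed_fit(gene, len(pts), pts))
        else:
            fits.append(fit_huber_line(pts))
    return call_confidence(fits)


def fits_to_frame(fits: list[MeanVarianceFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [f.gene_id for f in fits],
            "alpha": [f.alpha for f in fits],
            "alpha0": [f.alpha0 for f in fits],
            "se_alpha": [f.se_alpha for f in fits],
            "se_alpha0": [f.se_alpha0 for f in fits],
            "p_alpha": [f.p_alpha for f in fits],
            "q_alpha": [f.q_alpha for f in fits],
            "p_alpha0": [f.p_alpha0 for f in fits],
            "q_alpha0": [f.q_alpha0 for f in fits],
            "r2": [f.r2 for f in fits],
            "n_conditions": [f.n_conditions for f in fits],
            "confidence_class": [f.confidence_class for f in fits],
        }
    )
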