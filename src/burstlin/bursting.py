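"""Burst statistics implied by linear mean-variance constraints.

Moment estimators quantify burstiness per condition: burst size
b_s = sigma^2 / mu (the Fano factor, 1 for Poisson production) and
burst frequency b_f = mu / b_s = mu^2 / sigma^2.  Under the empirical
linear constraint sigma^2 = alpha * mu + alpha0 these become analytic
functions of the mean,

    b_s(mu) = alpha0 / mu + alpha,
    b_f(mu) = mu^2 / (alpha0 + alpha * mu),

and, eliminating the mean, b_f = alpha0 / (b_s (b_s - alpha)).  For a
positive intercept, burst size decreases monotonically towards alpha as
expression rises (an inverse size/frequency relationship); for a
negative intercept the line is defined only for mu > |alpha0|/alpha,
burst size rises towards alpha, and burst frequency has a local minimum
at mu* = 2|alpha0|/alpha of height 4|alpha0|/alpha^2 — equivalently a
minimum of b_f over b_s at b_s* = alpha/2.  Genes are classified by
where their observed burst sizes sit relative to alpha/2 (inverse,
U-shape, concurrent) and by which statistic changes more across
conditions (frequency- vs size-dominant modulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mean_variance import ConditionMoments, MeanVarianceFit

__all__ = [
    "BurstEstimates",
    "ModulationScheme",
    "moment_burst",
    "burst_estimates",
    "theoretical_curves",
    "bs_bf_relation",
    "rrmse",
    "modulation_fold_changes",
    "classify_mode",
    "mu_grid",
    "summarize_gene",
]

DOMINANCE_FOLD = 2.0


@dataclass(frozen=True)
class BurstEstimates:
    """Moment-estimator burst statistics for one condition."""

    gene_id: str
    condition: object
    mu: float
    var: float
    bs: float
    bf: float


@dataclass
class ModulationScheme:
    """Analytic modulation curves and labels for one gene."""

    gene_id: str
    alpha: float
    alpha0: float
    mus: np.ndarray
    bs_curve: np.ndarray
    bf_curve: np.ndarray
    mode: str = "unassessed"
    dominance: str = "unassessed"
    delta_bs: float = np.nan
    delta_bf: float = np.nan
    modulation_ratio: float = np.nan
    abs_difference: float = np.nan
    n_excluded: int = 0
    estimates: list[BurstEstimates] = field(default_factory=list, repr=False)


def moment_burst(mu: float, var: float) -> tuple[float, float]:
    """Burst size sigma^2/mu and burst frequency mu^2/sigma^2.

    Undefined (NaN) when the mean or variance is zero.
    """

    if mu <= 0 or var <= 0:
        return np.nan, np.nan
    return var / mu, mu * mu / var


def burst_estimates(moments: list[ConditionMoments]) -> list[BurstEstimates]:
    out = []
    for m in moments:
        bs, bf = moment_burst(m.mu, m.var)
        out.append(
            BurstEstimates(
                gene_id=m.gene_id, condition=m.condition, mu=m.mu, var=m.var,
                bs=bs, bf=bf,
            )
        )
    return out


def _domain_lower(alpha: float, alpha0: float) -> float:
    """Lower end of the mu-domain of the constrained curves."""

    if alpha0 < 0:
        return -alpha0 / alpha
    return 0.0


def mu_grid(fit: MeanVarianceFit, n_points: int = 200) -> np.ndarray:
    """Mean grid spanning the observed range, clipped to the curve domain."""

    obs = np.array([m.mu for m in fit.moments if m.mu > 0])
    if obs.size == 0:
        raise ValueError("no observed means to span")
    lo = max(_domain_lower(fit.alpha, fit.alpha0) * 1.01, obs.min())
    hi = obs.max()
    if hi <= lo:
        hi = lo * 1.5
    return np.linspace(lo, hi, n_points)


def theoretical_curves(
    fit: MeanVarianceFit, mus: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate b_s(mu) and b_f(mu) on a grid; out-of-domain points dropped.

    Returns (mus_kept, bs, bf).
    """

    mus = np.asarray(mus, dtype=float)
    alpha, alpha0 = fit.alpha, fit.alpha0
    var = alpha * mus + alpha0
    ok = (mus > 0) & (var > 0)
    mus = mus[ok]
    var = var[ok]
    bs = alpha0 / mus + alpha
    bf = mus * mus / var
    return mus, bs, bf


def bs_bf_relation(fit: MeanVarianceFit, bs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """b_f as a function of b_s: alpha0 / (b_s (b_s - alpha)).

    Domain: b_s > alpha when alpha0 > 0; 0 < b_s < alpha when
    alpha0 < 0.  The pole b_s = alpha is excluded.  Returns
    (bs_kept, bf).
    """

    alpha, alpha0 = fit.alpha, fit.alpha0
    if alpha0 == 0:
        raise ValueError("b_f(b_s) is undefined for a zero intercept")
    bs = np.asarray(bs, dtype=float)
    if alpha0 > 0:
        ok = bs > alpha
    else:
        ok = (bs > 0) & (bs < alpha)
    bs = bs[ok]
    return bs, alpha0 / (bs * (bs - alpha))


def rrmse(model: np.ndarray, data: np.ndarray) -> float:
    """Relative root mean square error, in percent.

    sqrt(sum((data - model)^2) / N) / sqrt(sum(model^2)) * 100.
    """

    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if model.shape != data.shape or model.size == 0:
        raise ValueError("model and data must be equal-length, non-empty")
    denom = np.sqrt(np.sum(model**2))
    if denom == 0:
        return np.nan
    return float(np.sqrt(np.mean((data - model) ** 2)) / denom * 100.0)


def modulation_fold_changes(
    estimates: list[BurstEstimates],
) -> tuple[float, float, float, str]:
    """Relative fold changes of burst size and frequency across conditions.

    delta_x = (max x - min x) / min x; the modulation ratio is
    delta_bf / delta_bs.  Dominance: frequency if the ratio exceeds 2,
    size if below 1/2, comparable otherwise.  Conditions with undefined
    estimators are excluded by the caller.
    """

    bs = np.array([e.bs for e in estimates])
    bf = np.array([e.bf for e in estimates])
    if bs.size < 2:
        raise ValueError("need >= 2 conditions with defined estimates")
    if bs.min() <= 0 or bf.min() <= 0:
        return np.nan, np.nan, np.nan, "undefined"
    delta_bs = (bs.max() - bs.min()) / bs.min()
    delta_bf = (bf.max() - bf.min()) / bf.min()
    if delta_bs == 0:
        ratio = np.inf if delta_bf > 0 else np.nan
    else:
        ratio = delta_bf / delta_bs
    if np.isnan(ratio):
        dominance = "comparable"
    elif ratio > DOMINANCE_FOLD:
        dominance = "frequency"
    elif ratio < 1.0 / DOMINANCE_FOLD:
        dominance = "size"
    else:
        dominance = "comparable"
    return float(delta_bs), float(delta_bf), float(ratio), dominance


def classify_mode(
    fit: MeanVarianceFit,
    estimates: list[BurstEstimates],
    treat_nonsig_intercept_as_zero: bool = False,
) -> str:
    """Modulation mode from the intercept sign and observed burst sizes.

    alpha0 > 0: inverse.  alpha0 < 0: U_shape when the observed burst
    sizes straddle alpha/2, inverse when all sit below alpha/2, else
    concurrent.  A (numerically or statistically) zero intercept means
    pure frequency modulation at constant burst size.
    """

    alpha0 = fit.alpha0
    if treat_nonsig_intercept_as_zero and not (fit.q_alpha0 < 0.05):
        alpha0 = 0.0
    if alpha0 == 0:
        return "frequency_only"
    if alpha0 > 0:
        return "inverse"
    bs = np.array([e.bs for e in estimates if np.isfinite(e.bs)])
    if bs.size < 2:
        return "undefined"
    half = fit.alpha / 2.0
    if bs.max() > half and bs.min() < half:
        return "U_shape"
    if bs.max() < half:
        return "inverse"
    return "concurrent"


def summarize_gene(
    fit: MeanVarianceFit, n_grid: int = 200
) -> ModulationScheme:
    """Full modulation summary: curves, RRMSEs inputs, mode and dominance."""

    est_all = burst_estimates(fit.moments)
    excluded = [e for e in est_all if not np.isfinite(e.bs)]
    est = [e for e in est_all if np.isfinite(e.bs)]
    grid = mu_grid(fit, n_grid)
    mus, bs_curve, bf_curve = theoretical_curves(fit, grid)
    scheme = ModulationScheme(
        gene_id=fit.gene_id,
        alpha=fit.alpha,
        alpha0=fit.alpha0,
        mus=mus,
        bs_curve=bs_curve,
        bf_curve=bf_curve,
        n_excluded=len(excluded),
        estimates=est,
    )
    if len(est) >= 2:
        delta_bs, delta_bf, ratio, dominance = modulation_fold_changes(est)
        scheme.delta_bs = delta_bs
        scheme.delta_bf = delta_bf
        scheme.modulation_ratio = ratio
        scheme.dominance = dominance
        bs_arr = np.array([e.bs for e in est])
        bf_arr = np.array([e.bf for e in est])
        scheme.abs_difference = float(
            abs((bs_arr.max() - bs_arr.min()) - (bf_arr.max() - bf_arr.min()))
        )
    scheme.mode = classify_mode(fit, est)
    return scheme


def gene_rrmse(fit: MeanVarianceFit) -> dict[str, float]:
    """RRMSE of the fitted line and the derived burst curves vs the data.

    Evaluated at the observed condition means, per gene across its
    conditions.
    """

    est = [e for e in burst_estimates(fit.moments) if np.isfinite(e.bs)]
    mus = np.array([e.mu for e in est])
    var_model = fit.alpha * mus + fit.alpha0
    _, bs_model, bf_model = theoretical_curves(fit, mus)
    var_data = np.array([e.var for e in est])
    bs_data = np.array([e.bs for e in est])
    bf_data = np.array([e.bf for e in est])
    keep = var_model > 0
    return {
        "rrmse_meanvar": rrmse(var_model[keep], var_data[keep]),
        "rrmse_bs": rrmse(bs_model, bs_data[keep]),
        "rrmse_bf": rrmse(bf_model, bf_data[keep]),
    }
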