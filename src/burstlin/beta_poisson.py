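"""Steady-state Beta-Poisson model of the 2-state telegraph process.

At stationarity the per-allele mRNA count of a 2-state telegraph gene is
Poisson with a Beta-distributed intensity:

    P(k) = Integral_0^1 Poisson(k; k_t u) Beta(u; k_on, k_off) du,

with all rates expressed in units of the degradation rate k_d (i.e. per
mRNA lifetime).  The two-allele distribution is the self-convolution of
the per-allele pmf.  The quadrature uses Gauss-Jacobi nodes, which
absorb the Beta weight exactly, with adaptive node doubling.

Maximum-likelihood fitting is over log-parameters with moment-matched
initialisation; a fit is flagged unconverged when the optimiser fails,
sticks to its bounds, or the condition is uninformative (too few cells
or near-zero mean), mirroring the role of a keep/discard flag in
profile-likelihood implementations of the same model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, roots_jacobi

__all__ = [
    "BetaPoissonParams",
    "bp_pmf",
    "bp_pmf_vector",
    "bp_loglik",
    "fit_bp_ml",
    "coverage_select",
    "COVERAGE_THRESHOLDS",
]

# minimum count of fitted conditions per species for the
# high-coverage gene set (out of ~20/21 mouse/rat, 12 pig/rabbit)
COVERAGE_THRESHOLDS = {"mouse": 10, "rat": 10, "pig": 6, "rabbit": 6}

MIN_CELLS = 50
MIN_MEAN = 0.1

_LOG_BOUNDS = (np.log(1e-3), np.log(1e4))


@dataclass(frozen=True)
class BetaPoissonParams:
    """2-state stationary rates in units of the degradation rate."""

    k_on: float
    k_off: float
    k_t: float

    def __post_init__(self) -> None:
        if min(self.k_on, self.k_off, self.k_t) <= 0:
            raise ValueError("all Beta-Poisson parameters must be > 0")

    def mean_per_allele(self) -> float:
        return self.k_t * self.k_on / (self.k_on + self.k_off)

    def to_rates(self, k_d: float):
        """Convert to absolute per-minute rates given a degradation rate."""
        return self.k_on * k_d, self.k_off * k_d, self.k_t * k_d

    @classmethod
    def from_rates(cls, k_on: float, k_off: float, k_t: float, k_d: float):
        return cls(k_on / k_d, k_off / k_d, k_t / k_d)


def _pmf_single(N: int, params: BetaPoissonParams, n_nodes: int) -> np.ndarray:
    a, b, kt = params.k_on, params.k_off, params.k_t
    x, w = roots_jacobi(n_nodes, b - 1.0, a - 1.0)
    u = (1.0 + x) / 2.0
    lam = kt * u  # Poisson intensity at each node
    k = np.arange(N + 1)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pois = k * np.log(lam[None, :]) - lam[None, :] - gammaln(k + 1.0)
    log_pois = np.where((lam[None, :] == 0) & (k > 0), -np.inf, log_pois)
    log_pois = np.where((lam[None, :] == 0) & (k == 0), 0.0, log_pois)
    pois = np.exp(log_pois)
    norm = np.exp(-(a + b - 1.0) * np.log(2.0) - betaln(a, b))
    return np.clip(norm * (pois @ w), 0.0, None)


def bp_pmf_vector(
    N: int,
    params: BetaPoissonParams,
    n_alleles: int = 2,
    rtol: float = 1e-9,
    n_nodes: int | None = None,
) -> np.ndarray:
    """Per-allele (or convolved two-allele) pmf over counts 0..N(*n_alleles).

    With ``n_nodes`` unset the node count doubles until the pmf is
    stable to ``rtol`` (raises if not converged by 512 nodes); a fixed
    node count skips the adaptivity (used inside fitting loops, where
    quadrature error well below the sampling noise suffices).
    """

    if n_nodes is not None:
        with np.errstate(over="ignore", invalid="ignore"):
            prev = _pmf_single(N, params, n_nodes)
        if not np.all(np.isfinite(prev)):
            raise RuntimeError(f"quadrature failed for {params}")
    else:
        n = 32
        prev = _pmf_single(N, params, n)
        while n < 512:
            n *= 2
            cur = _pmf_single(N, params, n)
            if np.max(np.abs(cur - prev)) < rtol:
                prev = cur
                break
            prev = cur
        else:
            raise RuntimeError(f"quadrature did not converge for {params}")
    pmf = prev
    if n_alleles == 2:
        pmf = np.convolve(pmf, pmf)
    return pmf


def bp_pmf(k: int, params: BetaPoissonParams, n_alleles: int = 2) -> float:
    """Probability of observing ``k`` total mRNA."""

    if k < 0:
        raise ValueError("k must be >= 0")
    per_allele_N = k if n_alleles == 1 else k
    return float(bp_pmf_vector(per_allele_N, params, n_alleles=n_alleles)[k])


def _truncation_for(params: BetaPoissonParams, max_obs: int) -> int:
    mean = params.mean_per_allele()
    return int(max(max_obs, np.ceil(4 * mean + 30)))


def bp_loglik(
    counts: np.ndarray, params: BetaPoissonParams, n_nodes: int | None = None
) -> float:
    counts = np.asarray(counts, dtype=int)
    N1 = _truncation_for(params, int(counts.max()))
    pmf = bp_pmf_vector(N1, params, n_alleles=2, n_nodes=n_nodes)
    probs = pmf[counts]
    if (probs <= 0).any():
        return -np.inf
    return float(np.log(probs).sum())


def _moment_init(counts: np.ndarray) -> BetaPoissonParams:
    m = counts.mean()
    v = counts.var(ddof=1)
    m1 = max(m / 2.0, 1e-3)  # per-allele mean
    fano = max(v / m if m > 0 else 1.0, 1.01)
    kt0 = max(4.0 * fano, 2.0 * m1, 1.0)
    b0 = 3.0
    frac = min(m1 / kt0, 0.9)
    a0 = b0 * frac / (1.0 - frac)
    return BetaPoissonParams(max(a0, 1e-3), b0, kt0)


def fit_bp_ml(
    counts: np.ndarray, min_cells: int = MIN_CELLS
) -> tuple[BetaPoissonParams | None, bool]:
    """Bounded ML fit of the two-allele Beta-Poisson model.

    Returns (params, converged).  ``converged`` is False when there are
    fewer than ``min_cells`` observations, the sample mean is below
    0.1, the optimiser fails, or the optimum sits on a parameter bound
    (the parameters are then unidentifiable from the data).
    """

    counts = np.asarray(counts, dtype=int)
    if counts.size < min_cells:
        return None, False
    if counts.mean() < MIN_MEAN or counts.max() == 0:
        return None, False
    init = _moment_init(counts)
    starts = [
        np.log([init.k_on, init.k_off, init.k_t]),
        # burstier alternative basin: rarer, larger bursts
        np.log([init.k_on / 3.0, init.k_off * 3.0, init.k_t * 2.0]),
    ]
    lo, hi = _LOG_BOUNDS

    def nll(logx: np.ndarray) -> float:
        p = BetaPoissonParams(*np.exp(logx))
        try:
            ll = bp_loglik(counts, p, n_nodes=128)
        except RuntimeError:
            # quadrature cannot resolve extreme corner parameters;
            # treat them as arbitrarily poor fits
            return 1e12
        return -ll if np.isfinite(ll) else 1e12

    best, success = None, False
    for x0 in starts:
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * 3,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best, success = res, bool(res.success)
    # simplex polish: L-BFGS on a quadrature-evaluated surface can
    # stall short of the optimum
    res2 = minimize(
        nll, best.x, method="Nelder-Mead",
        options={"maxfev": 250, "xatol": 1e-6, "fatol": 1e-7},
    )
    if res2.fun < best.fun:
        best, success = res2, True
    params = BetaPoissonParams(*np.exp(np.clip(best.x, lo, hi)))
    on_bound = bool(np.any(best.x <= lo + 1e-6) or np.any(best.x >= hi - 1e-6))
    converged = success and not on_bound
    return params, converged


def coverage_select(
    flags: dict[str, pd.DataFrame],
    thresholds: dict[str, int] | None = None,
) -> pd.DataFrame:
    """High-coverage gene calls per species.

    ``flags`` maps species to a genes x conditions boolean frame of
    converged fits.  A gene passes in a species when its converged-
    condition count reaches the species threshold (defaults: 10 for
    mouse and rat, 6 for pig and rabbit).
    """

    thresholds = thresholds or COVERAGE_THRESHOLDS
    out = {}
    for species, frame in flags.items():
        if species not in thresholds:
            raise KeyError(f"no coverage threshold for species {species!r}")
        out[species] = frame.sum(axis=1) >= thresholds[species]
    return pd.DataFrame(out)
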