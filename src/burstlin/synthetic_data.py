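"""Synthetic count datasets with known ground truth.

Three generator families:

* exact stochastic simulation (SSA) of the telegraph models, and i.i.d.
  sampling from their CME distributions — parameter-recovery material
  for the dynamical fitting stage;
* negative-binomial "linear family" genes whose condition-level variance
  follows sigma^2 = alpha * mu + alpha0 by construction — material for
  the mean-variance regression and bursting-modulation stages;
* multi-species panels with species-specific slopes — material for the
  cross-species divergence stage.

Datasets mimic the structure of a stimulation time-course experiment:
conditions are (treatment, time, replicate) triples, ~12-21 per species,
with UMI-scale overdispersed counts.  All generators are deterministic
given their seed; per-cell SSA streams are derived from the master seed
so cell simulations are order-independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .cme_models import (
    CMEDistribution,
    TelegraphParams,
    TelegraphParams2,
    TelegraphParams3,
    solve_model,
)
from .dataio import CountDataset

__all__ = [
    "simulate_ssa",
    "sample_from_cme",
    "sample_from_distribution",
    "generate_linear_family",
    "generate_species_panel",
    "DEFAULT_MUS",
    "SPECIES_MUS",
    "STUDY_CONDITION_COUNTS",
]

# Default per-gene mean grid across stimulation conditions: roughly
# geometric over ~1.5 orders of magnitude, matching the induction range
# of a typical stimulus-responsive gene over a 0-6 h time course.
DEFAULT_MUS = np.array([5.0, 8.0, 13.0, 21.0, 34.0, 55.0, 90.0, 145.0])

# Default mean grid for cross-species panels.  Slope comparisons between
# species assume comparable residual noise across conditions; because the
# sampling noise of a sample variance scales with sigma^2 itself, panels
# meant for slope t-tests keep a modest (~2x) dynamic range of means.
SPECIES_MUS = np.array([25.0, 28.0, 32.0, 36.0, 40.0, 45.0, 50.0, 55.0])

# Conditions per species in a four-species stimulation panel
# (treatment x time x replicate triples actually present per species).
STUDY_CONDITION_COUNTS = {"mouse": 20, "rat": 21, "pig": 12, "rabbit": 12}


@njit(cache=True)
def _ssa_kernel(seeds, S, tr, k_d, t_end, n_alleles):  # pragma: no cover - jitted
    n_cells = seeds.shape[0]
    n_s = S.shape[0]
    out = np.empty(n_cells, dtype=np.int64)
    for i in range(n_cells):
        np.random.seed(seeds[i])
        total = 0
        for _a in range(n_alleles):
            s = 0  # promoter off
            m = 0
            t = 0.0
            while True:
                r_sw = -S[s, s]
                r_birth = tr[s]
                r_death = m * k_d
                rate = r_sw + r_birth + r_death
                if rate == 0.0:
                    break
                t += np.random.exponential(1.0 / rate)
                if t > t_end:
                    break
                u = np.random.random() * rate
                if u < r_sw:
                    acc = 0.0
                    for j in range(n_s):
                        if j == s:
                            continue
                        acc += S[j, s]
                        if u < acc:
                            s = j
                            break
                elif u < r_sw + r_birth:
                    m += 1
                else:
                    m -= 1
            total += m
        out[i] = total
    return out


def _cell_seeds(seed: int, n_cells: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n_cells, dtype=np.uint32)


def simulate_ssa(
    params: TelegraphParams,
    t: float,
    n_cells: int,
    seed: int,
    n_alleles: int = 2,
) -> np.ndarray:
    """Exact event-driven simulation of mRNA totals at time ``t`` (minutes).

    Each cell starts with no mRNA and all alleles off, and carries an
    independent random stream derived from the master seed, so results
    are reproducible and independent of simulation order.
    """

    if t < 0:
        raise ValueError("t must be >= 0")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    S = np.ascontiguousarray(params.switching_matrix())
    tr = np.ascontiguousarray(params.transcription_rates())
    seeds = _cell_seeds(seed, n_cells)
    return _ssa_kernel(seeds, S, tr, float(params.k_d), float(t), int(n_alleles))


def sample_from_cme(
    params: TelegraphParams,
    t: float,
    n_cells: int,
    seed: int,
    n_alleles: int = 2,
) -> np.ndarray:
    """I.i.d. draws from the CME distribution P(X, t).

    Truncation is enlarged automatically until the tail mass criterion
    is met, so draws come from a distribution normalised to within 1e-6.
    """

    dist = solve_model(params, t, n_alleles=n_alleles)
    return sample_from_distribution(dist, n_cells, seed)


def sample_from_distribution(
    dist: CMEDistribution, n_cells: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    cdf = dist.cdf()
    cdf = cdf / cdf[-1]
    u = rng.random(n_cells)
    return np.searchsorted(cdf, u, side="left").astype(np.int64)


def _nb_draw(
    rng: np.random.Generator, mu: float, var: float, n: int
) -> np.ndarray:
    """Counts with the requested mean and variance.

    Negative binomial for var > mu; the Poisson limit when var == mu
    (within float tolerance).
    """

    if var < mu - 1e-9:
        raise ValueError(f"infeasible condition: variance {var} < mean {mu}")
    if var <= mu * (1 + 1e-9):
        return rng.poisson(mu, size=n)
    r = mu * mu / (var - mu)
    p = mu / var
    return rng.negative_binomial(r, p, size=n)


def _condition_labels(n: int) -> list[tuple[str, float, str]]:
    """Unique (treatment, time_h, replicate) triples in study style."""

    labels = []
    treatments = ("LPS", "PIC")
    times = (2.0, 4.0, 6.0)
    rep = 1
    while len(labels) < n:
        for tr in treatments:
            for tm in times:
                labels.append((tr, tm, f"r{rep}"))
                if len(labels) == n:
                    return labels
        rep += 1
    return labels


def _assemble_dataset(
    counts_per_condition: list[np.ndarray],
    n_genes: int,
    species: str,
) -> CountDataset:
    """Stack per-condition (n_genes x n_cells) blocks into a CountDataset."""

    import pandas as pd

    labels = _condition_labels(len(counts_per_condition))
    blocks = []
    meta_rows = []
    cell_counter = 0
    for block, (tr, tm, rep) in zip(counts_per_condition, labels):
        blocks.append(block)
        for _ in range(block.shape[1]):
            meta_rows.append(
                {
                    "cell_id": f"{species}_c{cell_counter}",
                    "species": species,
                    "treatment": tr,
                    "time_h": tm,
                    "replicate": rep,
                }
            )
            cell_counter += 1
    counts = np.concatenate(blocks, axis=1)
    meta = pd.DataFrame(meta_rows)
    gene_ids = [f"g{i:03d}" for i in range(n_genes)]
    return CountDataset(counts=counts, gene_ids=gene_ids, cell_meta=meta)


def _check_feasible(alpha: float, alpha0: float, mus: np.ndarray) -> None:
    for mu in mus:
        var = alpha * mu + alpha0
        if not var > mu:
            raise ValueError(
                f"infeasible (mu={mu}, alpha={alpha}, alpha0={alpha0}): "
                f"target variance {var} must exceed the mean for an "
                "overdispersed count family"
            )
        if mu <= 0 or var <= 0:
            raise ValueError(f"mu={mu} outside the domain of the line")


def generate_linear_family(
    alpha: float,
    alpha0: float,
    mus: np.ndarray | list[float] = DEFAULT_MUS,
    n_cells: int = 2000,
    seed: int = 0,
    n_genes: int = 1,
    species: str = "mouse",
    n_background: int = 0,
    background_mean: float = 20.0,
) -> CountDataset:
    """Genes whose condition-level variance is alpha * mu + alpha0 exactly.

    One condition per requested mean; counts are negative binomial with
    the target mean and variance (Poisson in the alpha=1, alpha0=0
    limit).  Condition-level sample moments converge to the target line
    as ``n_cells`` grows.

    ``n_background`` appends condition-independent Poisson genes
    (ids ``bg...``) emulating the non-responsive transcriptome that
    dominates per-cell library depth; required when the dataset is to
    be median-scaled, since depth estimation needs genes whose
    expression does not follow the stimulus.
    """

    mus = np.asarray(mus, dtype=float)
    if alpha == 1.0 and alpha0 == 0.0:
        pass  # Poisson limit: variance == mean is allowed
    else:
        _check_feasible(alpha, alpha0, mus)
    rng = np.random.default_rng(seed)
    blocks = []
    for mu in mus:
        var = alpha * mu + alpha0
        block = np.stack(
            [_nb_draw(rng, mu, var, n_cells) for _ in range(n_genes)], axis=0
        )
        if n_background:
            bg = rng.poisson(background_mean, size=(n_background, n_cells))
            block = np.concatenate([block, bg], axis=0)
        blocks.append(block)
    ds = _assemble_dataset(blocks, n_genes + n_background, species)
    if n_background:
        ds.gene_ids = [f"g{i:03d}" for i in range(n_genes)] + [
            f"bg{i:03d}" for i in range(n_background)
        ]
    return ds


def generate_species_panel(
    slopes: dict[str, float] | list[float],
    alpha0: float = 0.0,
    mus: np.ndarray | list[float] = SPECIES_MUS,
    n_cells: int = 2000,
    seed: int = 0,
    n_genes: int = 1,
    gene_alphas: np.ndarray | list[float] | None = None,
    n_conditions: dict[str, int] | None = None,
) -> dict[str, CountDataset]:
    """One dataset per species with species-specific mean-variance slopes.

    ``slopes`` gives each species' slope (or a per-species multiplier of
    ``gene_alphas`` when per-gene base slopes are supplied).  All species
    share the mean grid; when a species has more conditions than grid
    points the grid recycles with fresh replicate labels, mirroring
    replicated time courses.
    """

    if isinstance(slopes, (list, tuple, np.ndarray)):
        slopes = {f"species{i + 1}": s for i, s in enumerate(slopes)}
    mus = np.asarray(mus, dtype=float)
    if gene_alphas is None:
        gene_alphas = np.ones(n_genes)
    gene_alphas = np.asarray(gene_alphas, dtype=float)
    if len(gene_alphas) != n_genes:
        raise ValueError("gene_alphas must have n_genes entries")
    master = np.random.SeedSequence(seed)
    panel: dict[str, CountDataset] = {}
    for child, (species, slope) in zip(master.spawn(len(slopes)), slopes.items()):
        if slope <= 0:
            raise ValueError(f"slope for {species} must be > 0")
        n_cond = (n_conditions or {}).get(species, len(mus))
        species_mus = mus[np.arange(n_cond) % len(mus)]
        for g_alpha in gene_alphas:
            _check_feasible(slope * g_alpha, alpha0, species_mus)
        rng = np.random.default_rng(child)
        blocks = []
        for mu in species_mus:
            block = np.stack(
                [
                    _nb_draw(rng, mu, slope * g_alpha * mu + alpha0, n_cells)
                    for g_alpha in gene_alphas
                ],
                axis=0,
            )
            blocks.append(block)
        panel[species] = _assemble_dataset(blocks, n_genes, species)
    return panel
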