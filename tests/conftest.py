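import numpy as np
import pandas as pd
import pytest

from burstlin.dataio import CountDataset, identity_normalize

np.seterr(over="ignore", under="ignore")


@pytest.fixture(scope="session")
def huber_recovery_hits() -> tuple[int, int]:
    """Seeds (of 100) where the Huber slope lands within +/-10% of truth
    on an 8-condition, 20,000-cell linear family."""
    from burstlin.mean_variance import fit_gene_panel
    from burstlin.synthetic_data import generate_linear_family

    ok = 0
    for seed in range(100):
        ds = generate_linear_family(3.0, 0.0, n_cells=20_000, seed=seed)
        fit = fit_gene_panel(identity_normalize(ds))[0]
        ok += 2.7 <= fit.alpha <= 3.3
    return ok, 100


@pytest.fixture(scope="session")
def null_ttest_rejections() -> tuple[int, int]:
    """Slope t-test rejections on same-slope species panels (seeds 0..499).

    Computed once per session; asserted by the unit and acceptance
    suites.
    """
    from burstlin.evolution import slope_ttest
    from burstlin.mean_variance import fit_gene_panel
    from burstlin.synthetic_data import generate_species_panel

    n_seeds = 500
    rej = 0
    for seed in range(n_seeds):
        panel = generate_species_panel({"A": 3.0, "B": 3.0}, n_cells=2000, seed=seed)
        fa = fit_gene_panel(identity_normalize(panel["A"]))[0]
        fb = fit_gene_panel(identity_normalize(panel["B"]))[0]
        rej += slope_ttest(fa, fb, ("A", "B")).p < 0.05
    return rej, n_seeds


@pytest.fixture
def tiny_dataset() -> CountDataset:
    """3 genes x 4 cells in 2 conditions."""

    counts = np.array(
        [
            [0, 1, 2, 3],
            [4, 0, 1, 5],
            [2, 2, 2, 2],
        ]
    )
    meta = pd.DataFrame(
        {
            "cell_id": ["c0", "c1", "c2", "c3"],
            "species": ["mouse"] * 4,
            "treatment": ["LPS", "LPS", "PIC", "PIC"],
            "time_h": [2.0, 2.0, 4.0, 4.0],
            "replicate": ["r1", "r1", "r1", "r1"],
        }
    )
    return CountDataset(counts=counts, gene_ids=["g0", "g1", "g2"], cell_meta=meta)
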