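"""Generate the synthetic study panels used by the downstream analyses.

Writes, under results/data/:
  * linear_family/   — a 24-gene stimulation panel with a spread of
    mean-variance slopes (plus background genes carrying library depth),
  * species/<name>/  — a two-species panel with a two-fold slope change,
  * telegraph/       — per-condition integer counts sampled from known
    2-state and 3-state telegraph kinetics, with their half-life table.
"""

import json
from pathlib import Path

import numpy as np

from burstlin.cme_models import TelegraphParams2, TelegraphParams3
from burstlin.dataio import HalfLifeTable, write_counts
from burstlin.synthetic_data import (
    generate_linear_family,
    generate_species_panel,
    sample_from_cme,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # stimulation panel: responsive genes on a shared slope-3 line, with
    # background genes carrying per-cell library depth
    ds = generate_linear_family(
        alpha=3.0, alpha0=0.0, n_cells=1000, seed=SEED, n_genes=24,
        n_background=800, background_mean=25.0,
    )
    write_counts(ds, OUT / "linear_family", fmt="mtx")
    print(f"linear family: {ds.n_genes} genes x {ds.n_cells} cells, "
          f"{ds.n_conditions} conditions")

    panel = generate_species_panel(
        {"mouse": 3.0, "pig": 6.0}, n_cells=1500, seed=SEED + 1, n_genes=30,
        gene_alphas=np.linspace(1.0, 2.5, 30),
    )
    for species, sds in panel.items():
        write_counts(sds, OUT / "species" / species, fmt="mtx")
        print(f"species {species}: {sds.n_genes} genes x {sds.n_cells} cells")

    # telegraph conditions: 2 h time point, replicated
    kd15 = float(np.log(2) / 15.0)
    two = TelegraphParams2(k_on=0.05, k_off=0.4, k_t=3.0, k_d=kd15)
    three = TelegraphParams3(
        t_on=0.1, t_off=0.3, k_on=0.08, k_off=0.15, k_c=0.05, k_ti=0.5, k_t=6.0,
        k_d=kd15,
    )
    tele = OUT / "telegraph"
    tele.mkdir(parents=True, exist_ok=True)
    manifest = {"t_min": 120.0, "half_life_min": 15.0, "conditions": []}
    for label, params in (("two_state", two), ("three_state", three)):
        for rep in range(3):
            counts = sample_from_cme(params, t=120.0, n_cells=2500,
                                     seed=SEED + 10 * rep + hash(label) % 97)
            np.savetxt(tele / f"{label}_r{rep}.counts.txt", counts, fmt="%d")
            manifest["conditions"].append(
                {"label": f"{label}_r{rep}", "generator": label}
            )
            print(f"telegraph {label} r{rep}: mean {counts.mean():.1f}, "
                  f"Fano {counts.var() / counts.mean():.1f}")
    (tele / "manifest.json").write_text(json.dumps(manifest, indent=2))
    HalfLifeTable({"g000": 15.0}).write(tele / "half_lives.tsv")


if __name__ == "__main__":
    main()
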