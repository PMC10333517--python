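# burstlin

Single-cell mRNA counts of stimulus-responsive genes are noisy in a
structured way: across stimulation conditions (ligand, time point,
replicate), a gene's count variance grows approximately linearly with
its mean,

    sigma^2 = alpha * mu + alpha0,

and the slope alpha summarises how heterogeneously cells respond.
`burstlin` turns that observation into an analysis toolkit for
innate-immune (or any stimulation) scRNA-seq time courses:

* **Mean-variance layer** — robust (Huber) per-gene fits of the linear
  constraint across conditions, with FDR-corrected slope significance
  and an R^2 > 0.6 high-confidence call.
* **Bursting layer** — under the constraint, the moment estimators of
  burst size (b_s = sigma^2/mu, the Fano factor) and burst frequency
  (b_f = mu^2/sigma^2) become analytic functions of the mean:
  b_s = alpha0/mu + alpha, b_f = mu^2/(alpha0 + alpha mu), and
  b_f = alpha0/(b_s(b_s - alpha)).  Genes classify into inverse,
  U-shape and concurrent modulation modes, with frequency- vs
  size-dominance calls and RRMSE agreement between theory and data.
* **Mechanistic layer** — 2-state and 3-state telegraph promoter
  models (two independent alleles) solved exactly through the chemical
  master equation, fitted per condition by a genetic algorithm on a
  CDF distance, compared by AIC with a multinomial likelihood; plus
  the stationary Beta-Poisson model with maximum-likelihood fitting.
* **Evolution layer** — pairwise slope t-tests between species,
  divergence stratification at a two-fold slope change, response
  divergence scores, and the correlation between slope ratios and
  3-state-model prevalence.
* **Synthetic-data generator** — exact stochastic simulation and CME
  sampling of the telegraph models, negative-binomial linear families
  and multi-species panels with known ground truth, so every stage has
  parameter-recovery tests without any data download.

The scientific background and all numerical choices are described in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from burstlin.dataio import identity_normalize
from burstlin.mean_variance import fit_gene_panel
from burstlin.bursting import summarize_gene, gene_rrmse
from burstlin.synthetic_data import generate_linear_family

# one gene, 8 stimulation conditions on the line sigma^2 = 3 mu
ds = generate_linear_family(alpha=3.0, alpha0=0.0, n_cells=20_000, seed=1)
fit = fit_gene_panel(identity_normalize(ds))[0]
print(f"alpha = {fit.alpha:.2f}, alpha0 = {fit.alpha0:.2f}, "
      f"R^2 = {fit.r2:.4f}, class = {fit.confidence_class}")
scheme = summarize_gene(fit)
print(f"mode = {scheme.mode}, dominance = {scheme.dominance}")
print({k: round(v, 2) for k, v in gene_rrmse(fit).items()})
```

prints

```
alpha = 2.96, alpha0 = 0.12, R^2 = 0.9999, class = high_confidence
mode = inverse, dominance = frequency
{'rrmse_meanvar': 0.21, 'rrmse_bs': 0.29, 'rrmse_bf': 0.21}
```

i.e. the generated slope is recovered within ~1.5%, the fitted
intercept is indistinguishable from zero (so burst size is nearly
constant and the gene is frequency-modulated), and the analytic
modulation curves agree with the per-condition moment estimators to a
fraction of a percent.

The numbered drivers under `analysis/` run the full narrative on
synthetic panels — `01_simulate_data.py` (generate), `02_mean_variance.py`
(fit lines), `03_bursting_modes.py` (modulation), `04_model_selection.py`
(2- vs 3-state AIC selection), `05_species_divergence.py`
(cross-species slopes) — each printing what it found and writing
tables under `results/`.

A `burstlin` command-line interface wraps the same pipeline for use on
files (`burstlin normalize | simulate | meanvar | bursting |
fit-dynamic | compare-species`; see `burstlin --help`).

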