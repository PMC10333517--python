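"""Panel-level drivers combining the per-module operations.

These are the units of work the analysis scripts (and the heavier
integration tests) run: fit mean-variance lines for every gene of a
dataset, summarise bursting modulation, and run 2-state vs 3-state
model selection over a list of conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursting import gene_rrmse, summarize_gene
from .dataio import NormalizedDataset
from .dynamic_fit import (
    GAConfig,
    fit_both_models,
    fit_condition_ml,
    filter_aic_outliers,
    select_model,
)
from .mean_variance import MeanVarianceFit, fit_gene_panel, fits_to_frame

__all__ = [
    "mean_variance_study",
    "bursting_table",
    "ConditionSpec",
    "model_selection_study",
]


def mean_variance_study(nds: NormalizedDataset) -> tuple[list[MeanVarianceFit], pd.DataFrame]:
    """Per-gene robust mean-variance fits with confidence calls."""

    fits = fit_gene_panel(nds)
    return fits, fits_to_frame(fits)


def bursting_table(fits: list[MeanVarianceFit]) -> pd.DataFrame:
    """Per-gene modulation summary: mode, dominance, fold changes, RRMSE."""

    rows = []
    for fit in fits:
        if fit.failed or fit.confidence_class == "failed":
            continue
        scheme = summarize_gene(fit)
        row = {
            "gene_id": fit.gene_id,
            "alpha": fit.alpha,
            "alpha0": fit.alpha0,
            "mode": scheme.mode,
            "dominance": scheme.dominance,
            "delta_bs": scheme.delta_bs,
            "delta_bf": scheme.delta_bf,
            "modulation_ratio": scheme.modulation_ratio,
            "n_excluded": scheme.n_excluded,
        }
        row.update(gene_rrmse(fit))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ConditionSpec:
    """One condition entering model selection."""

    label: str
    counts: np.ndarray
    t: float
    k_d: float
    gene_id: str = "gene"
    species: str = "A"


def model_selection_study(
    conditions: list[ConditionSpec],
    method: str = "ga",
    ga: GAConfig | None = None,
    seed: int = 0,
    apply_outlier_filter: bool = True,
    ml_starts: int = 4,
) -> pd.DataFrame:
    """Fit both telegraph models per condition and select by AIC.

    ``method`` is "ga" (the reference protocol: CDF-distance genetic
    algorithm, ML-seeded) or "ml" (direct maximum likelihood; faster,
    used for large panels).  Returns one row per condition with AICs,
    retention flags after the per-family Tukey filter, and winners
    under the absolute and factor-two rules.
    """

    rows = []
    for i, spec in enumerate(conditions):
        if method == "ga":
            r2, r3 = fit_both_models(
                spec.counts, spec.t, spec.k_d, ga=ga, seed=seed + 2 * i
            )
        elif method == "ml":
            r2 = fit_condition_ml(
                spec.counts, spec.t, spec.k_d, "two_state",
                seed=seed + 2 * i, n_starts=ml_starts,
            )
            r3 = fit_condition_ml(
                spec.counts, spec.t, spec.k_d, "three_state",
                seed=seed + 2 * i, n_starts=ml_starts,
            )
        else:
            raise ValueError("method must be 'ga' or 'ml'")
        rows.append(
            {
                "label": spec.label,
                "gene_id": spec.gene_id,
                "species": spec.species,
                "t": spec.t,
                "aic_2": r2.aic if r2 else np.nan,
                "aic_3": r3.aic if r3 else np.nan,
                "objective_2": r2.objective if r2 else np.nan,
                "objective_3": r3.objective if r3 else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    frame["retained_2"] = True
    frame["retained_3"] = True
    if apply_outlier_filter and len(frame) >= 4:
        frame["retained_2"] = filter_aic_outliers(frame["aic_2"].to_numpy())
        frame["retained_3"] = filter_aic_outliers(frame["aic_3"].to_numpy())
    sel_abs, sel_half = [], []
    for _, row in frame.iterrows():
        a2 = row["aic_2"] if row["retained_2"] else np.nan
        a3 = row["aic_3"] if row["retained_3"] else np.nan
        sel_abs.append(select_model(a2, a3, "absolute"))
        sel_half.append(select_model(a2, a3, "half"))
    frame["selected_absolute"] = sel_abs
    frame["selected_half"] = sel_half
    return frame
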