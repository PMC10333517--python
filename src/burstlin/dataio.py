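"""Reading, writing and normalisation of UMI count matrices.

A dataset is a genes x cells integer UMI count matrix with per-cell
metadata (species, treatment, time in hours, replicate).  Cells are
partitioned into *conditions* by the (treatment, time_h, replicate)
triple; all per-gene statistics downstream are computed within these
condition groups.

Normalisation is median scaling per cell: every cell's counts are
multiplied by (median total count across cells) / (cell total), so that
post-scaling totals all equal the median pre-scaling total.  Model
fitting uses an integer view obtained by rounding the scaled values
half-up.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

ConditionKey = tuple[str, float, str]

META_COLUMNS = ["cell_id", "species", "treatment", "time_h", "replicate"]


@dataclass
class CountDataset:
    """Integer UMI counts (genes x cells) plus per-cell condition labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    conditions: dict[ConditionKey, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if len(self.cell_meta) != n_cells:
            raise ValueError(
                f"metadata has {len(self.cell_meta)} rows but matrix has "
                f"{n_cells} cell columns"
            )
        _validate_counts(self.counts, self.cell_meta)
        if not self.conditions:
            self.conditions = _partition(self.cell_meta)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass
class NormalizedDataset:
    """Median-scaled counts with an integer view for model fitting."""

    scaled: np.ndarray
    integer_view: np.ndarray
    scale_factors: np.ndarray
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    conditions: dict[ConditionKey, np.ndarray]

    @property
    def n_genes(self) -> int:
        return self.scaled.shape[0]

    @property
    def n_cells(self) -> int:
        return self.scaled.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None


@dataclass(frozen=True)
class HalfLifeTable:
    """Per-gene mRNA half-lives (minutes) and implied degradation rates."""

    half_life_min: dict[str, float]

    def __post_init__(self) -> None:
        for gene, t_half in self.half_life_min.items():
            if not t_half > 0:
                raise ValueError(f"half-life of {gene!r} must be > 0")

    def k_d(self, gene: str) -> float:
        """Degradation rate per minute: k_d = log(2) / t_1/2."""
        return float(np.log(2.0) / self.half_life_min[gene])

    @classmethod
    def read(cls, path: str | Path) -> "HalfLifeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float))))

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.half_life_min), "half_life_min": list(self.half_life_min.values())}
        ).to_csv(path, sep="\t", index=False)


def half_life_from_rate(k: float) -> float:
    """Half-time (minutes) of a first-order rate k (per minute): ln(2)/k."""

    if not k > 0:
        raise ValueError("rate must be > 0")
    return float(np.log(2.0) / k)


def _validate_counts(counts: np.ndarray, cell_meta: pd.DataFrame) -> None:
    if not np.issubdtype(counts.dtype, np.integer):
        if not np.allclose(counts, np.round(counts)):
            bad = np.argwhere(counts != np.round(counts))
            g, c = bad[0]
            cell = cell_meta["cell_id"].iloc[c] if "cell_id" in cell_meta else c
            raise ValueError(
                f"non-integer count {counts[g, c]} at gene row {g}, cell {cell!r}"
            )
    if (counts < 0).any():
        bad = np.argwhere(counts < 0)
        g, c = bad[0]
        cell = cell_meta["cell_id"].iloc[c] if "cell_id" in cell_meta else c
        raise ValueError(f"negative count at gene row {g}, cell {cell!r}")


def _partition(cell_meta: pd.DataFrame) -> dict[ConditionKey, np.ndarray]:
    missing = [c for c in ("treatment", "time_h", "replicate") if c not in cell_meta]
    if missing:
        raise ValueError(f"metadata lacks condition columns: {missing}")
    groups: dict[ConditionKey, np.ndarray] = {}
    keys = list(
        zip(
            cell_meta["treatment"].astype(str),
            cell_meta["time_h"].astype(float),
            cell_meta["replicate"].astype(str),
        )
    )
    order: dict[ConditionKey, list[int]] = {}
    for i, key in enumerate(keys):
        order.setdefault(key, []).append(i)
    for key, idx in order.items():
        groups[key] = np.asarray(idx, dtype=int)
    return groups


def read_counts(
    matrix_path: str | Path,
    meta_path: str | Path,
    expected_conditions: list[ConditionKey] | None = None,
) -> CountDataset:
    """Read an MTX or CSV count matrix with its TSV cell metadata.

    MTX matrices are genes x cells; CSV matrices have a header row of
    cell ids and a first column of gene ids.  Metadata rows must match
    the cell columns in order.
    """

    matrix_path = Path(matrix_path)
    meta = pd.read_csv(meta_path, sep="\t")
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        if sp.issparse(mat):
            mat = mat.toarray()
        counts = np.asarray(mat)
        genes_file = matrix_path.with_name(matrix_path.stem + ".genes.tsv")
        if genes_file.exists():
            gene_ids = pd.read_csv(genes_file, sep="\t", header=None)[0].astype(str).tolist()
        else:
            gene_ids = [f"gene{i}" for i in range(counts.shape[0])]
    else:
        df = pd.read_csv(matrix_path, index_col=0)
        counts = df.to_numpy()
        gene_ids = df.index.astype(str).tolist()
    if counts.shape[1] != len(meta):
        raise ValueError(
            f"dimension mismatch: matrix has {counts.shape[1]} cells, "
            f"metadata has {len(meta)} rows"
        )
    if np.issubdtype(counts.dtype, np.floating):
        _validate_counts(counts, meta)
        counts = np.round(counts).astype(np.int64)
    ds = CountDataset(counts=counts, gene_ids=gene_ids, cell_meta=meta)
    if expected_conditions is not None:
        empty = [k for k in expected_conditions if k not in ds.conditions]
        if empty:
            raise ValueError(f"conditions with no cells: {empty}")
    logger.info(
        "read %d genes x %d cells in %d conditions",
        ds.n_genes,
        ds.n_cells,
        ds.n_conditions,
    )
    return ds


def write_counts(ds: CountDataset, out_dir: str | Path, fmt: str = "mtx") -> None:
    """Write a dataset as counts.{mtx|csv} + meta.tsv (+ gene id sidecar for MTX)."""

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        scipy.io.mmwrite(out / "counts.mtx", sp.coo_matrix(ds.counts))
        pd.Series(ds.gene_ids).to_csv(
            out / "counts.genes.tsv", sep="\t", index=False, header=False
        )
    elif fmt == "csv":
        pd.DataFrame(
            ds.counts, index=ds.gene_ids, columns=ds.cell_meta["cell_id"].astype(str)
        ).to_csv(out / "counts.csv")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    ds.cell_meta.to_csv(out / "meta.tsv", sep="\t", index=False)


def median_scale(ds: CountDataset) -> NormalizedDataset:
    """Median-scale counts per cell.

    scale_factors[c] = median(total counts) / total(cell c); cells with
    zero total get factor 1 (with a warning) rather than being dropped.
    """

    totals = ds.counts.sum(axis=0).astype(float)
    positive = totals > 0
    if not positive.any():
        raise ValueError("no cell has a positive total count")
    median_total = float(np.median(totals[positive]))
    factors = np.ones_like(totals)
    factors[positive] = median_total / totals[positive]
    n_zero = int((~positive).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} cell(s) with zero total count kept with scale factor 1",
            stacklevel=2,
        )
    scaled = ds.counts * factors[None, :]
    integer_view = np.floor(scaled + 0.5).astype(np.int64)  # round half-up
    return NormalizedDataset(
        scaled=scaled,
        integer_view=integer_view,
        scale_factors=factors,
        gene_ids=list(ds.gene_ids),
        cell_meta=ds.cell_meta,
        conditions=dict(ds.conditions),
    )


def identity_normalize(ds: CountDataset) -> NormalizedDataset:
    """Wrap a dataset with unit scale factors (counts already comparable).

    Synthetic datasets are generated on a common depth by construction,
    so median scaling (which needs genome-wide per-cell totals to
    estimate depth) does not apply; this provides the normalised view
    without rescaling.
    """

    return NormalizedDataset(
        scaled=ds.counts.astype(float),
        integer_view=ds.counts.astype(np.int64),
        scale_factors=np.ones(ds.n_cells),
        gene_ids=list(ds.gene_ids),
        cell_meta=ds.cell_meta,
        conditions=dict(ds.conditions),
    )


def condition_counts(
    nds: NormalizedDataset,
    gene: str,
    condition: ConditionKey,
    view: str = "scaled",
) -> np.ndarray:
    """Per-cell values of one gene in one condition, from the requested view."""

    gi = nds.gene_index(gene)
    if condition not in nds.conditions:
        raise KeyError(f"unknown condition {condition!r}")
    idx = nds.conditions[condition]
    if view == "scaled":
        return nds.scaled[gi, idx]
    if view == "integer":
        return nds.integer_view[gi, idx]
    raise ValueError("view must be 'scaled' or 'integer'")


def write_normalized(nds: NormalizedDataset, out_dir: str | Path) -> None:
    """Persist a normalised dataset as CSV/TSV tables."""

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = nds.cell_meta["cell_id"].astype(str)
    pd.DataFrame(nds.scaled, index=nds.gene_ids, columns=cells).to_csv(
        out / "scaled.csv"
    )
    pd.DataFrame(nds.integer_view, index=nds.gene_ids, columns=cells).to_csv(
        out / "integer.csv"
    )
    pd.DataFrame({"cell_id": cells, "scale_factor": nds.scale_factors}).to_csv(
        out / "scale_factors.tsv", sep="\t", index=False
    )
    nds.cell_meta.to_csv(out / "meta.tsv", sep="\t", index=False)


def read_normalized(in_dir: str | Path) -> NormalizedDataset:
    src = Path(in_dir)
    scaled = pd.read_csv(src / "scaled.csv", index_col=0)
    integer = pd.read_csv(src / "integer.csv", index_col=0)
    factors = pd.read_csv(src / "scale_factors.tsv", sep="\t")
    meta = pd.read_csv(src / "meta.tsv", sep="\t")
    return NormalizedDataset(
        scaled=scaled.to_numpy(),
        integer_view=integer.to_numpy().astype(np.int64),
        scale_factors=factors["scale_factor"].to_numpy(),
        gene_ids=scaled.index.astype(str).tolist(),
        cell_meta=meta,
        conditions=_partition(meta),
    )


def write_manifest(path: str | Path, seed: int, config: dict) -> None:
    """JSON run manifest recording the seed and configuration."""

    import burstlin

    payload = {"seed": seed, "config": config, "version": burstlin.__version__}
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
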