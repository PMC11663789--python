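"""QC filtering, log-normalization, metabolic subsetting and NMF-input scaling."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from metahet.io_core import CellExpression, GeneSet

logger = logging.getLogger(__name__)

MITO_PREFIX = "MT-"


class EmptyResultError(ValueError):
    """A filtering step removed everything."""


@dataclasses.dataclass
class QCConfig:
    min_genes: int = 200
    min_umi: int = 500
    max_mito_fraction: float = 0.10
    #: optional per-sample relaxation of the mito cap, each value <= 0.40
    mito_overrides: dict[str, float] = dataclasses.field(default_factory=dict)
    max_cells_per_dataset: int = 100_000
    min_cells_per_sample: int = 20

    def __post_init__(self) -> None:
        if min(self.min_genes, self.min_umi, self.max_cells_per_dataset) <= 0:
            raise ValueError("QC thresholds must be positive")
        if not 0 < self.max_mito_fraction <= 0.40:
            raise ValueError("max_mito_fraction must be in (0, 0.40]")
        for sample, cap in self.mito_overrides.items():
            if cap > 0.40:
                raise ValueError(f"mito override for {sample} exceeds 0.40")


@dataclasses.dataclass
class NormalizedMatrix:
    """Log-normalized expression: sparse cells x genes plus labels."""

    matrix: sp.csr_matrix
    gene_symbols: np.ndarray
    cell_ids: pd.Index
    scale: float = 1e4

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.cell_ids, columns=self.gene_symbols
        )

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        idx = self.cell_ids.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            raise KeyError("unknown cell ids")
        return NormalizedMatrix(
            self.matrix[idx], self.gene_symbols, self.cell_ids[idx], self.scale
        )


def detected_genes(x: CellExpression) -> np.ndarray:
    return np.asarray((x.counts > 0).sum(axis=1)).ravel()


def total_umi(x: CellExpression) -> np.ndarray:
    return np.asarray(x.counts.sum(axis=1)).ravel()


def mito_fraction(x: CellExpression, mito_genes: list[str] | None = None) -> np.ndarray:
    """Per-cell mitochondrial read fraction; genes found by MT- prefix unless given."""
    if mito_genes is None:
        mask = np.array([str(s).startswith(MITO_PREFIX) for s in x.gene_symbols])
    else:
        wanted = set(mito_genes)
        mask = np.array([s in wanted for s in x.gene_symbols])
    tot = total_umi(x).astype(float)
    if not mask.any():
        return np.zeros(x.n_cells)
    mito = np.asarray(x.counts[:, np.flatnonzero(mask)].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(tot > 0, mito / tot, 0.0)
    return frac


def qc_filter(
    x: CellExpression,
    cfg: QCConfig | None = None,
    seed: int = 0,
    mito_genes: list[str] | None = None,
) -> tuple[CellExpression, pd.DataFrame]:
    """Drop low-quality cells, then downsample each dataset to its cap.

    Cells with fewer than ``min_genes`` detected genes or ``min_umi`` total
    counts, or above the (possibly per-sample overridden) mito cap, are
    removed.  Each dataset is then uniformly downsampled without replacement
    to ``max_cells_per_dataset`` (seeded).  Returns the filtered cohort and a
    per-cell QC report for the retained cells.
    """
    cfg = cfg or QCConfig()
    n_det = detected_genes(x)
    n_umi = total_umi(x)
    m_frac = mito_fraction(x, mito_genes)
    caps = x.cell_meta["sample_id"].map(
        lambda s: cfg.mito_overrides.get(s, cfg.max_mito_fraction)
    ).to_numpy(dtype=float)
    keep = (n_det >= cfg.min_genes) & (n_umi >= cfg.min_umi) & (m_frac <= caps)
    if not keep.any():
        raise EmptyResultError("QC filtering removed all cells")

    # seeded uniform per-dataset downsampling
    rng = np.random.default_rng(seed)
    keep_idx = np.flatnonzero(keep)
    datasets = x.cell_meta["dataset_id"].to_numpy()
    selected: list[np.ndarray] = []
    for ds in pd.unique(datasets[keep_idx]):
        ds_idx = keep_idx[datasets[keep_idx] == ds]
        if len(ds_idx) > cfg.max_cells_per_dataset:
            ds_idx = np.sort(rng.choice(ds_idx, cfg.max_cells_per_dataset, replace=False))
            logger.info("downsampled dataset %s to %d cells", ds, len(ds_idx))
        selected.append(ds_idx)
    final_idx = np.sort(np.concatenate(selected))
    logger.info("qc_filter: retained %d / %d cells", len(final_idx), x.n_cells)

    out = x.subset_cells(x.cell_meta.index[final_idx])
    report = pd.DataFrame(
        {
            "n_genes_detected": n_det[final_idx],
            "n_umi": n_umi[final_idx],
            "mito_fraction": m_frac[final_idx],
            "sample_id": x.cell_meta["sample_id"].to_numpy()[final_idx],
            "dataset_id": datasets[final_idx],
        },
        index=x.cell_meta.index[final_idx],
    )
    return out, report


def lognormalize(x: CellExpression, scale: float = 1e4) -> NormalizedMatrix:
    """``log(1 + scale * count / cell_total)`` per entry (natural log).

    Per-cell totals of the pre-log values equal ``scale`` exactly.
    """
    totals = total_umi(x).astype(float)
    if (totals <= 0).any():
        raise EmptyResultError("zero-total cell encountered; run QC first")
    mat = x.counts.tocsr().astype(float, copy=True)
    inv = scale / totals
    mat = sp.diags(inv) @ mat
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        matrix=sp.csr_matrix(mat),
        gene_symbols=x.gene_symbols.copy(),
        cell_ids=x.cell_meta.index.copy(),
        scale=scale,
    )


def select_metabolic(
    x: NormalizedMatrix, metabolic_genes: GeneSet, top_n: int = 500
) -> pd.DataFrame:
    """Keep the ``top_n`` metabolic genes by mean normalized expression.

    Ties at the cutoff are broken toward the lexicographically smaller
    symbol.  Returns a dense cells x genes frame (genes in rank order).
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    wanted = set(metabolic_genes.genes)
    mask = np.array([s in wanted for s in x.gene_symbols])
    if not mask.any():
        raise EmptyResultError("no metabolic genes present in the matrix")
    idx = np.flatnonzero(mask)
    means = np.asarray(x.matrix[:, idx].mean(axis=0)).ravel()
    order = sorted(range(len(idx)), key=lambda i: (-means[i], str(x.gene_symbols[idx[i]])))
    chosen = idx[np.asarray(order[:top_n], dtype=np.intp)]
    return pd.DataFrame(
        x.matrix[:, chosen].toarray(),
        index=x.cell_ids,
        columns=x.gene_symbols[chosen],
    )


def scale_and_clip(x: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across cells, then set negatives to zero.

    Zero-variance genes become all-zero columns.  Uses the population
    standard deviation (ddof=0).
    """
    if x.shape[0] < 2:
        raise ValueError("scaling needs at least 2 cells")
    vals = x.to_numpy(dtype=float)
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[:, sd == 0] = 0.0
    np.clip(z, 0.0, None, out=z)
    return pd.DataFrame(z, index=x.index, columns=x.columns)
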