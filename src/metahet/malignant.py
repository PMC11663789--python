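"""Malignant vs non-malignant epithelium: CNV-lite profiles, the quadratic
CNV score, the iterative score-based 2-means classifier, and CD4/CD8 T-cell
assignment."""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from metahet.io_core import CellExpression
from metahet.preprocess import lognormalize
from metahet import scoring

logger = logging.getLogger(__name__)

CNV_CLAMP = 3.0

CD3_GENES = ("CD3D", "CD3E", "CD3G")
CD4_GENES = ("CD4",)
CD8_GENES = ("CD8A", "CD8B")


class DegenerateInputError(ValueError):
    """Score space has no structure to cluster."""


@dataclasses.dataclass
class CNVProfile:
    """Per-cell smoothed relative expression over genomically ordered genes."""

    values: np.ndarray  # cells x positioned genes
    gene_symbols: np.ndarray
    chromosomes: np.ndarray
    cell_ids: pd.Index
    window: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("CNV profile contains non-finite values")


@dataclasses.dataclass
class MalignancyCall:
    labels: pd.Series  # 'malignant' / 'non_malignant'
    malignant_score: pd.Series
    nonmalignant_score: pd.Series
    n_iterations: int
    final_misclassification_rate: float
    converged: bool


# ---------------------------------------------------------------------------
# CNV-lite
# ---------------------------------------------------------------------------


def _window_mean_within_chrom(vals: np.ndarray, chrom_sizes: list[int], window: int) -> np.ndarray:
    """Centred sliding-window mean per chromosome, truncated at bounds."""
    half = window // 2
    out = np.empty_like(vals)
    offset = 0
    for size in chrom_sizes:
        block = vals[:, offset : offset + size]
        csum = np.cumsum(block, axis=1)
        csum = np.concatenate([np.zeros((block.shape[0], 1)), csum], axis=1)
        lo = np.maximum(np.arange(size) - half, 0)
        hi = np.minimum(np.arange(size) + half + 1, size)
        out[:, offset : offset + size] = (csum[:, hi] - csum[:, lo]) / (hi - lo)
        offset += size
    return out


def infer_cnv_lite(
    x: CellExpression, reference_cells, window: int = 101
) -> CNVProfile:
    """Lightweight copy-number signal: reference-subtracted log expression,
    smoothed by a centred moving average within each chromosome, per-cell
    median-centred and clamped to +/-3.

    ``reference_cells`` are presumed diploid (e.g. normal epithelium).
    """
    if x.gene_positions is None:
        raise ValueError("gene positions required for CNV inference")
    ref_ids = pd.Index(reference_cells)
    if len(ref_ids) == 0:
        raise ValueError("reference cell set is empty")
    pos = x.gene_positions
    positioned = pos["chromosome"].notna().to_numpy()
    if not positioned.any():
        raise ValueError("no positioned genes")

    # genomic order: chromosome (natural order of appearance), then start
    idx = np.flatnonzero(positioned)
    chrom = pos["chromosome"].to_numpy()[idx]
    start = pos["start"].to_numpy()[idx].astype(float)
    chrom_order = {c: i for i, c in enumerate(pd.unique(chrom))}
    order = np.lexsort((start, np.array([chrom_order[c] for c in chrom])))
    idx = idx[order]
    chrom = chrom[order]

    norm = lognormalize(x)
    dense = norm.matrix[:, idx].toarray()
    ref_idx = norm.cell_ids.get_indexer(ref_ids)
    if (ref_idx < 0).any():
        raise KeyError("reference cells not present in the matrix")
    dense -= dense[ref_idx].mean(axis=0)

    chrom_sizes = [int(n) for n in pd.Series(chrom).groupby(chrom, sort=False).size()]
    smooth = _window_mean_within_chrom(dense, chrom_sizes, window)
    smooth -= np.median(smooth, axis=1, keepdims=True)
    np.clip(smooth, -CNV_CLAMP, CNV_CLAMP, out=smooth)
    return CNVProfile(
        values=smooth,
        gene_symbols=x.gene_symbols[idx],
        chromosomes=chrom,
        cell_ids=norm.cell_ids,
        window=window,
    )


def cnv_score(p: CNVProfile) -> pd.Series:
    """Quadratic sum of the smoothed CNV values, per cell."""
    return pd.Series(np.sum(p.values**2, axis=1), index=p.cell_ids, name="cnv_score")


# ---------------------------------------------------------------------------
# iterative malignancy classification
# ---------------------------------------------------------------------------


def _mean_expression(frame: pd.DataFrame, genes: list[str]) -> np.ndarray:
    cols = [g for g in genes if g in frame.columns]
    if not cols:
        return np.zeros(len(frame))
    return frame[cols].to_numpy().mean(axis=1)


def _two_means(points: np.ndarray, seed: int) -> np.ndarray:
    """2-means over score space: one init at the score-space extremes plus
    seeded random restarts; returns binary labels (best inertia)."""
    if np.allclose(points, points[0]):
        raise DegenerateInputError("all score points identical; cannot cluster")
    extreme = np.vstack(
        [
            points[np.argmax(points[:, 0] - points[:, 1])],
            points[np.argmax(points[:, 1] - points[:, 0])],
        ]
    )
    best = None
    km_ext = KMeans(n_clusters=2, init=extreme, n_init=1, random_state=seed).fit(points)
    best = km_ext
    km_rand = KMeans(n_clusters=2, init="random", n_init=9, random_state=seed).fit(points)
    if km_rand.inertia_ < best.inertia_:
        best = km_rand
    return best.labels_


def _top_signed_genes(de: pd.DataFrame, group: str, top_n: int) -> tuple[list[str], list[str]]:
    sub = de[de["group"] == group].copy()
    sub = sub.sort_values(["log2fc", "gene_or_set"], ascending=[False, True], kind="mergesort")
    sig = sub[sub["significant"]]
    up_pool = sig if len(sig) >= top_n else sub
    up = up_pool.head(top_n)["gene_or_set"].tolist()
    down = sub.tail(top_n)["gene_or_set"].tolist()[::-1]
    return up, down


def iterative_malignancy(
    x: CellExpression,
    initial_de: tuple[list[str], list[str]],
    top_n: int = 50,
    stop_rate: float = 0.001,
    max_iter: int = 20,
    seed: int = 0,
) -> MalignancyCall:
    """Iterative score-based 2-means labelling of epithelial cells.

    Each cell gets a malignant score (mean normalized expression of the top
    ``top_n`` upregulated genes) and a non-malignant score (top ``top_n``
    downregulated genes); 2-means on the 2-D score space yields putative
    labels (the cluster with higher mean malignant score is malignant); each
    round re-derives the signed gene lists by rank-sum DE between the
    putative groups, rebuilds scores and re-clusters, stopping when the
    fraction of labels changed versus the previous round drops below
    ``stop_rate``.  Non-convergence at ``max_iter`` is flagged, not raised.
    """
    up, down = list(initial_de[0]), list(initial_de[1])
    if not up or not down:
        raise ValueError("initial DE lists must be non-empty")
    frame = lognormalize(x).to_frame()

    def _score_and_cluster(up_g, down_g, it):
        mal = _mean_expression(frame, up_g[:top_n])
        nonmal = _mean_expression(frame, down_g[:top_n])
        raw = _two_means(np.column_stack([mal, nonmal]), seed=seed + it)
        mal_cluster = int(mal[raw == 1].mean() > mal[raw == 0].mean())
        return mal, nonmal, raw == mal_cluster

    # round 0: initial scores from the supplied signed lists
    mal, nonmal, labels = _score_and_cluster(up, down, 0)
    rate = 1.0
    converged = False
    n_iterations = 0
    for it in range(1, max_iter + 1):
        if labels.sum() < 3 or (~labels).sum() < 3:
            logger.warning("putative group below size 3; stopping refinement")
            break
        de = scoring.differential(
            frame, np.where(labels, "malignant", "non_malignant"), mode="gene"
        )
        up, down = _top_signed_genes(de, "malignant", top_n)
        if not up or not down:
            break
        mal, nonmal, new_labels = _score_and_cluster(up, down, it)
        rate = float(np.mean(new_labels != labels))
        labels = new_labels
        n_iterations = it
        if rate < stop_rate:
            converged = True
            break
    if not converged:
        logger.warning(
            "iterative_malignancy: no convergence after %d iterations", n_iterations
        )
    return MalignancyCall(
        labels=pd.Series(
            np.where(labels, "malignant", "non_malignant"),
            index=frame.index,
            name="malignancy",
        ),
        malignant_score=pd.Series(mal, index=frame.index, name="malignant_score"),
        nonmalignant_score=pd.Series(nonmal, index=frame.index, name="nonmalignant_score"),
        n_iterations=n_iterations,
        final_misclassification_rate=rate,
        converged=converged,
    )


def tumour_normal_de(
    x: CellExpression, top_n: int = 50
) -> tuple[list[str], list[str]]:
    """Signed DE gene lists from tumour-vs-normal pseudo-bulk rank-sum.

    Stand-in for an external bulk DE source: tests epithelial cells of
    tumour samples against those of normal samples.
    """
    frame = lognormalize(x).to_frame()
    tissue = x.cell_meta["tissue"].to_numpy()
    de = scoring.differential(frame, tissue, mode="gene")
    return _top_signed_genes(de, "tumour", top_n)


# ---------------------------------------------------------------------------
# T-cell subsets
# ---------------------------------------------------------------------------


def assign_t_subsets(x: CellExpression) -> pd.Series:
    """CD4/CD8 assignment from normalized marker means, rules applied verbatim:
    CD3>0 & CD4>0 & CD8==0 -> CD4; CD3>0 & CD4==0 & CD8>0 -> CD8; else
    unassigned."""
    symbols = set(x.gene_symbols)
    if "CD4" not in symbols or not symbols & set(CD3_GENES) or not symbols & set(CD8_GENES):
        raise ValueError("T-cell marker genes absent from the gene list")
    frame = lognormalize(x).to_frame()
    cd3 = _mean_expression(frame, list(CD3_GENES))
    cd4 = _mean_expression(frame, list(CD4_GENES))
    cd8 = _mean_expression(frame, list(CD8_GENES))
    labels = np.full(len(frame), "unassigned", dtype=object)
    labels[(cd3 > 0) & (cd4 > 0) & (cd8 == 0)] = "CD4"
    labels[(cd3 > 0) & (cd4 == 0) & (cd8 > 0)] = "CD8"
    return pd.Series(labels, index=frame.index, name="t_subset")
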