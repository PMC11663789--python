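"""Cell-type-specific pseudo-bulk, resampling consensus clustering and
cluster-signature derivation."""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from metahet.io_core import CellExpression, GeneSet
from metahet.preprocess import lognormalize
from metahet import scoring

logger = logging.getLogger(__name__)

PAC_LOWER = 0.1
PAC_UPPER = 0.9


class EmptyResultError(ValueError):
    pass


@dataclasses.dataclass
class PseudobulkMatrix:
    """Mean log-normalized expression per (sample, cell type)."""

    values: pd.DataFrame  # MultiIndex (sample_id, cell_type) x genes
    n_cells: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate (sample, cell type) rows")


@dataclasses.dataclass
class ConsensusResult:
    consensus_matrix: pd.DataFrame
    k: int
    labels: pd.Series  # cluster ids 1..k
    n_iterations: int
    resample_fraction: float
    pac_by_k: dict[int, float]


def build_pseudobulk(x: CellExpression, min_cells: int = 20) -> PseudobulkMatrix:
    """Average log-normalized expression over cells of each (sample, cell type).

    Groups with fewer than ``min_cells`` cells are omitted with a log entry.
    """
    if "cell_type" not in x.cell_meta.columns:
        raise ValueError("cell types must be assigned before pseudo-bulk")
    norm = lognormalize(x)
    meta = x.cell_meta
    keys = list(zip(meta["sample_id"], meta["cell_type"]))
    frame = pd.DataFrame(norm.matrix.toarray(), index=pd.MultiIndex.from_tuples(
        keys, names=["sample_id", "cell_type"]
    ), columns=norm.gene_symbols)
    sizes = frame.groupby(level=[0, 1]).size()
    keep = sizes[sizes >= min_cells].index
    dropped = sizes[sizes < min_cells]
    for key, n in dropped.items():
        logger.info("pseudo-bulk group %s omitted (%d cells < %d)", key, n, min_cells)
    if len(keep) == 0:
        raise EmptyResultError("no (sample, cell type) group reaches min_cells")
    means = frame.groupby(level=[0, 1]).mean().loc[keep]
    return PseudobulkMatrix(values=means, n_cells=sizes.loc[keep].rename("n_cells"))


def _hier_labels(dist_condensed: np.ndarray, k: int) -> np.ndarray:
    link = scipy.cluster.hierarchy.linkage(dist_condensed, method="average")
    return scipy.cluster.hierarchy.fcluster(link, t=k, criterion="maxclust")


def consensus_cluster(
    m: pd.DataFrame,
    k_range: Sequence[int],
    n_iter: int = 1000,
    resample: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Resampling consensus clustering with PAC-based choice of k.

    Per iteration, ``ceil(resample * n)`` items are drawn without
    replacement and clustered hierarchically (average linkage on 1 - Pearson
    distance); the consensus matrix is the ratio of co-clustering to
    co-sampling counts.  The k minimizing the proportion of ambiguous
    consensus values (PAC, entries in (0.1, 0.9)) wins; final labels come
    from clustering the consensus matrix at that k.
    """
    n = m.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if max(k_range) > n:
        raise ValueError("k_range exceeds item count")
    if n < 2 * max(k_range):
        raise ValueError(f"need >= {2 * max(k_range)} items for k up to {max(k_range)}")
    vals = m.to_numpy(dtype=float)
    n_sub = int(np.ceil(resample * n))
    rng = np.random.default_rng(seed)

    consensus_by_k: dict[int, np.ndarray] = {}
    pac_by_k: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(n_iter):
            idx = np.sort(rng.choice(n, n_sub, replace=False))
            sub = vals[idx]
            d = scipy.spatial.distance.pdist(sub, metric="correlation")
            labels = _hier_labels(np.clip(d, 0, None), k)
            same = labels[:, None] == labels[None, :]
            sampled[np.ix_(idx, idx)] += 1
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            cons = np.where(sampled > 0, together / sampled, 0.0)
        np.fill_diagonal(cons, 1.0)
        consensus_by_k[k] = cons
        off = cons[iu]
        pac_by_k[k] = float(np.mean((off > PAC_LOWER) & (off < PAC_UPPER)))

    best_k = min(k_range, key=lambda k: (pac_by_k[k], k))
    cons = consensus_by_k[best_k]
    dist = scipy.spatial.distance.squareform(1.0 - cons, checks=False)
    raw = _hier_labels(dist, best_k)
    # relabel clusters 1..k in order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, lab in enumerate(raw):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        labels[i] = remap[lab]
    return ConsensusResult(
        consensus_matrix=pd.DataFrame(cons, index=m.index, columns=m.index),
        k=best_k,
        labels=pd.Series(labels, index=m.index, name="cluster"),
        n_iterations=n_iter,
        resample_fraction=resample,
        pac_by_k=pac_by_k,
    )


def derive_subtype_signature(
    pb: PseudobulkMatrix, labels: pd.Series, min_members: int = 3
) -> dict[int, GeneSet | None]:
    """Per-cluster signature: significantly upregulated genes vs the rest.

    Reuses the rank-sum differential test in gene mode; clusters below
    ``min_members`` members are skipped.  A cluster with no significant genes
    maps to ``None`` (empty signature).
    """
    labels = labels.loc[pb.values.index]
    sizes = labels.value_counts()
    usable = sizes[sizes >= min_members]
    if len(usable) < 2:
        raise ValueError("need >= 2 clusters with enough members")
    mask = labels.isin(usable.index)
    de = scoring.differential(pb.values.loc[mask], labels[mask], mode="gene")
    out: dict[int, GeneSet | None] = {}
    for cluster in sorted(usable.index):
        up = de[(de["group"] == cluster) & de["significant"]]
        genes = sorted(up["gene_or_set"].tolist())
        out[int(cluster)] = (
            GeneSet(name=f"subtype_{cluster}", genes=genes, category="signature")
            if genes
            else None
        )
    return out
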