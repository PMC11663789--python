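"""Rank-based gene-set scoring and differential tests for cells and pseudo-bulk.

Per-cell scores follow the area-under-recovery-curve scheme (top-rank window,
normalized to [0,1]); pseudo-bulk scores are a signed standardized mean-rank
statistic.  Differential testing is Wilcoxon rank-sum with BH adjustment and
fold-change / expressed-fraction gates.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from metahet.io_core import CellExpression, GeneSet, ScoreMatrix, match_gene_sets
from metahet.preprocess import NormalizedMatrix, lognormalize

logger = logging.getLogger(__name__)

GENE_LFC_THRESHOLD = 0.1
SET_LFC_THRESHOLD = 0.01
FDR_THRESHOLD = 0.01
MIN_PCT = 0.10
LFC_EPS = 1e-9


@dataclasses.dataclass
class DifferentialRecord:
    gene_or_set: str
    group: str
    log2fc: float
    fdr: float
    pct_group1: float
    pct_group2: float
    significant: bool


# ---------------------------------------------------------------------------
# per-cell AUC scores
# ---------------------------------------------------------------------------


def _as_frame(x) -> pd.DataFrame:
    if isinstance(x, NormalizedMatrix):
        return x.to_frame()
    if isinstance(x, pd.DataFrame):
        return x
    raise TypeError(f"expected NormalizedMatrix or DataFrame, got {type(x).__name__}")


def aucell_score(
    x,
    sets: Iterable[GeneSet],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> ScoreMatrix:
    """Area under the set-recovery curve within the top-ranked gene window.

    Genes are ranked per cell by descending expression; ties are broken by a
    seeded random permutation fixed for the whole run.  The AUC over the top
    ``ceil(top_fraction * n_genes)`` ranks is normalized by its maximum so
    scores lie in [0, 1].
    """
    if not 0 < top_fraction <= 0.5:
        raise ValueError("top_fraction must be in (0, 0.5]")
    frame = _as_frame(x)
    vals = frame.to_numpy(dtype=float)
    n_cells, n_genes = vals.shape
    window = math.ceil(top_fraction * n_genes)
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(n_genes)

    # rank matrix: rank 1 = highest expression; ties resolved by `tiebreak`
    order = np.lexsort((np.broadcast_to(tiebreak, vals.shape), -vals), axis=1)
    ranks = np.empty_like(order)
    row = np.arange(n_cells)[:, None]
    ranks[row, order] = np.arange(1, n_genes + 1)[None, :]

    set_list = list(sets)
    set_idx = match_gene_sets(set_list, frame.columns)
    scores = np.zeros((n_cells, len(set_list)))
    for j, s in enumerate(set_list):
        idx = set_idx[s.name]
        if len(idx) == 0:
            logger.warning("gene set %r has no genes in the matrix; score 0", s.name)
            continue
        r = ranks[:, idx]
        inside = r <= window
        # each set gene at rank r contributes (window - r + 1) recovery steps
        auc = np.where(inside, window - r + 1, 0).sum(axis=1)
        k = min(len(idx), window)
        max_auc = k * window - (k * (k - 1)) // 2
        scores[:, j] = auc / max_auc
    return ScoreMatrix(
        pd.DataFrame(scores, index=frame.index, columns=[s.name for s in set_list])
    )


# ---------------------------------------------------------------------------
# pseudo-bulk scores (signed standardized mean-rank statistic)
# ---------------------------------------------------------------------------


def pseudobulk_score(pb: pd.DataFrame, sets: Iterable[GeneSet]) -> ScoreMatrix:
    """Signed per-(sample, set) statistic from within-sample gene ranks.

    For each sample the genes are rank-transformed (average ties); the score
    is the difference between the mean rank of set genes and of background
    genes, standardized by the rank variance.  Positive means the set is
    high in that sample; the statistic is antisymmetric under rank reversal.
    """
    if pb.shape[0] < 2:
        raise ValueError("pseudobulk_score needs >= 2 samples")
    vals = pb.to_numpy(dtype=float)
    n_samples, n_genes = vals.shape
    ranks = scipy.stats.rankdata(vals, axis=1)
    set_list = list(sets)
    set_idx = match_gene_sets(set_list, pb.columns)
    out = np.full((n_samples, len(set_list)), np.nan)
    var_all = ranks.var(axis=1, ddof=0)
    for j, s in enumerate(set_list):
        idx = set_idx[s.name]
        m = len(idx)
        b = n_genes - m
        if m == 0 or b == 0:
            logger.warning("gene set %r unusable for pseudobulk scoring", s.name)
            continue
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[idx] = True
        mean_set = ranks[:, in_set].mean(axis=1)
        mean_bg = ranks[:, ~in_set].mean(axis=1)
        denom = np.sqrt(var_all * (1.0 / m + 1.0 / b))
        out[:, j] = np.where(denom > 0, (mean_set - mean_bg) / denom, 0.0)
    return ScoreMatrix(pd.DataFrame(out, index=pb.index, columns=[s.name for s in set_list]))


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------


def _delog(vals: np.ndarray) -> np.ndarray:
    return np.expm1(vals)


def differential(
    x,
    group_labels: pd.Series | Sequence,
    mode: str = "gene",
    lfc_threshold: float | None = None,
    fdr_threshold: float = FDR_THRESHOLD,
    min_pct: float = MIN_PCT,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum tests with BH adjustment.

    ``mode='gene'`` operates on log-normalized expression (fold changes on
    the de-logged scale, expressed-fraction gate applies); ``mode='set'``
    operates on score matrices with the lower fold-change threshold and no
    expressed-fraction gate.  Groups with fewer than 3 units are skipped.
    """
    if mode not in ("gene", "set"):
        raise ValueError("mode must be 'gene' or 'set'")
    frame = _as_frame(x.values if isinstance(x, ScoreMatrix) else x)
    labels = pd.Series(np.asarray(group_labels), index=frame.index)
    if lfc_threshold is None:
        lfc_threshold = GENE_LFC_THRESHOLD if mode == "gene" else SET_LFC_THRESHOLD
    vals = frame.to_numpy(dtype=float)
    groups = [g for g in pd.unique(labels) if pd.notna(g)]
    if len(groups) < 2:
        raise ValueError("differential needs >= 2 groups")
    records: list[pd.DataFrame] = []
    for g in groups:
        in_g = (labels == g).to_numpy()
        if in_g.sum() < 3 or (~in_g).sum() < 3:
            logger.warning("group %r has < 3 units on one side; skipped", g)
            continue
        a, b = vals[in_g], vals[~in_g]
        res = scipy.stats.mannwhitneyu(
            a, b, axis=0, alternative="two-sided", method="asymptotic"
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        fdr = multipletests(pvals, method="fdr_bh")[1]
        if mode == "gene":
            mean_a = _delog(a).mean(axis=0)
            mean_b = _delog(b).mean(axis=0)
        else:
            mean_a = a.mean(axis=0)
            mean_b = b.mean(axis=0)
        log2fc = np.log2((mean_a + LFC_EPS) / (mean_b + LFC_EPS))
        pct_a = (a > 0).mean(axis=0)
        pct_b = (b > 0).mean(axis=0)
        sig = (log2fc > lfc_threshold) & (fdr < fdr_threshold)
        if mode == "gene":
            sig &= (pct_a > min_pct) | (pct_b > min_pct)
        records.append(
            pd.DataFrame(
                {
                    "gene_or_set": frame.columns,
                    "group": g,
                    "log2fc": log2fc,
                    "fdr": fdr,
                    "pct_group1": pct_a,
                    "pct_group2": pct_b,
                    "significant": sig,
                }
            )
        )
    if not records:
        raise ValueError("no testable groups (all below size 3)")
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# cell-to-cell metabolic similarity
# ---------------------------------------------------------------------------


def metabolic_similarity(x, n_pcs: int = 30) -> pd.DataFrame:
    """Spearman correlation of leading principal-component coordinates.

    Cells are embedded with PCA on (metabolic) gene expression; similarity of
    two cells is the Spearman correlation of their first ``n_pcs`` PC
    coordinates.  Symmetric with unit diagonal.
    """
    frame = _as_frame(x)
    if frame.shape[0] < n_pcs + 1:
        raise ValueError(f"need >= {n_pcs + 1} cells for {n_pcs} components")
    pcs = PCA(n_components=n_pcs, svd_solver="full").fit_transform(
        frame.to_numpy(dtype=float)
    )
    ranked = scipy.stats.rankdata(pcs, axis=1)
    sim = np.corrcoef(ranked)
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=frame.index, columns=frame.index)


# ---------------------------------------------------------------------------
# lineage prediction from metabolic expression
# ---------------------------------------------------------------------------


def lineage_auc(
    x: CellExpression,
    metabolic_genes: GeneSet,
    n_subsample: int = 10_000,
    seed: int = 0,
    cv_folds: int = 10,
) -> pd.DataFrame:
    """Held-out AUC of L1-regularized one-vs-rest lineage classifiers.

    Within each dataset the samples are split randomly (seeded) into two
    equal halves; up to ``n_subsample`` cells are drawn per half; the model
    trains on one half with cross-validated penalty and is evaluated on the
    other.  Lineages absent from either half are skipped.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    norm = lognormalize(x)
    wanted = set(metabolic_genes.genes)
    gmask = np.array([s in wanted for s in norm.gene_symbols])
    if not gmask.any():
        raise ValueError("no metabolic genes in the matrix")
    mat = norm.matrix[:, np.flatnonzero(gmask)].toarray()
    meta = x.cell_meta
    rows = []
    for ds in pd.unique(meta["dataset_id"]):
        ds_mask = (meta["dataset_id"] == ds).to_numpy()
        samples = pd.unique(meta.loc[ds_mask, "sample_id"])
        if len(samples) < 2:
            logger.warning("dataset %s has < 2 samples; skipped", ds)
            continue
        perm = rng.permutation(len(samples))
        half = len(samples) // 2
        train_samples = set(samples[perm[:half]])
        in_ds = np.flatnonzero(ds_mask)
        is_train = meta["sample_id"].to_numpy()[in_ds]
        train_idx = in_ds[np.isin(is_train, list(train_samples))]
        test_idx = np.setdiff1d(in_ds, train_idx)

        def _cap(idx: np.ndarray) -> np.ndarray:
            if len(idx) > n_subsample:
                return np.sort(rng.choice(idx, n_subsample, replace=False))
            return idx

        train_idx, test_idx = _cap(train_idx), _cap(test_idx)
        y_all = meta["cell_type"].to_numpy()
        for lineage in sorted(pd.unique(y_all[np.concatenate([train_idx, test_idx])])):
            y_train = (y_all[train_idx] == lineage).astype(int)
            y_test = (y_all[test_idx] == lineage).astype(int)
            if y_train.sum() in (0, len(y_train)) or y_test.sum() in (0, len(y_test)):
                logger.warning("lineage %s absent from a half in %s; skipped", lineage, ds)
                continue
            n_folds = min(cv_folds, max(2, int(np.bincount(y_train).min())))
            model = LogisticRegressionCV(
                Cs=5,
                cv=n_folds,
                penalty="l1",
                solver="liblinear",
                max_iter=200,
                random_state=int(rng.integers(2**31 - 1)),
            )
            model.fit(mat[train_idx], y_train)
            auc = roc_auc_score(y_test, model.predict_proba(mat[test_idx])[:, 1])
            rows.append({"dataset_id": ds, "lineage": lineage, "auc": float(auc)})
    return pd.DataFrame(rows, columns=["dataset_id", "lineage", "auc"])
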