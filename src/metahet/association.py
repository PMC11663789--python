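"""Correlation screens linking program/pathway scores to covariates, plus the
cross-cell-type co-occurrence network and variance-explained models."""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class CorrelationRecord:
    dataset_id: str
    mmp_or_pathway: str
    covariate: str
    per_tumour_r: list[float]
    mean_pearson_r: float
    p_pearson_adj: float
    p_spearman_adj: float
    significant: bool
    retained: bool = True


@dataclasses.dataclass
class CooccurrenceEdge:
    mmp_a: str
    mmp_b: str
    pearson_r: float
    p_value: float

    def __post_init__(self) -> None:
        if self.pearson_r <= 0:
            raise ValueError("co-occurrence edges must have positive correlation")
        if self.mmp_a == self.mmp_b:
            raise ValueError("self-edges are not allowed")


def _one_sided_t(rs: np.ndarray) -> float:
    """One-sided t-test that per-tumour coefficients differ from 0 in the
    direction of their mean."""
    if len(rs) < 2:
        return 1.0
    if np.allclose(rs, rs[0]):
        # degenerate spread: all coefficients (numerically) identical
        return 1.0 if np.isclose(np.mean(rs), 0.0) else 0.0
    direction = "greater" if np.mean(rs) >= 0 else "less"
    return float(scipy.stats.ttest_1samp(rs, 0.0, alternative=direction).pvalue)


def score_correlation(
    scores_a: Mapping[str, pd.DataFrame],
    scores_b: Mapping[str, pd.DataFrame],
    tumour_datasets: Mapping[str, str],
    r_threshold: float = 0.4,
    top_k: int | None = None,
    min_tumours: int = 3,
) -> pd.DataFrame:
    """Per-tumour Pearson/Spearman correlation screen between two score sets.

    ``scores_a``/``scores_b`` map tumour id to a units x sets frame sharing
    row units within each tumour.  Per (dataset, a-set, b-set): coefficients
    are computed per tumour (zero-variance tumours dropped with a warning),
    averaged, and tested against zero with a one-sided t-test; BH adjustment
    runs over all pairs, Pearson and Spearman separately.  A pair is
    significant when both adjusted p < 0.05 and |mean Pearson r| exceeds
    ``r_threshold``; with ``top_k`` set, only the top ``top_k`` significant
    pairs by |mean r| per (dataset, a-set) are retained.
    """
    tumours = sorted(set(scores_a) & set(scores_b))
    if not tumours:
        raise ValueError("no shared tumours between the two score collections")
    a_sets = list(next(iter(scores_a.values())).columns)
    b_sets = list(next(iter(scores_b.values())).columns)

    rows = []
    datasets = sorted({tumour_datasets[t] for t in tumours})
    for ds in datasets:
        ds_tumours = [t for t in tumours if tumour_datasets[t] == ds]
        for sa in a_sets:
            for sb in b_sets:
                pear, spear = [], []
                for t in ds_tumours:
                    fa, fb = scores_a[t], scores_b[t]
                    units = fa.index.intersection(fb.index)
                    va = fa.loc[units, sa].to_numpy(dtype=float)
                    vb = fb.loc[units, sb].to_numpy(dtype=float)
                    if len(units) < 3:
                        continue
                    if np.std(va) == 0 or np.std(vb) == 0:
                        logger.warning(
                            "zero-variance scores in tumour %s for (%s, %s); dropped", t, sa, sb
                        )
                        continue
                    pear.append(float(scipy.stats.pearsonr(va, vb).statistic))
                    spear.append(float(scipy.stats.spearmanr(va, vb).statistic))
                if len(pear) < min_tumours:
                    continue
                rows.append(
                    {
                        "dataset_id": ds,
                        "mmp_or_pathway": sa,
                        "covariate": sb,
                        "per_tumour_r": pear,
                        "mean_pearson_r": float(np.mean(pear)),
                        "p_pearson": _one_sided_t(np.asarray(pear)),
                        "p_spearman": _one_sided_t(np.asarray(spear)),
                    }
                )
    if not rows:
        return pd.DataFrame(
            columns=[
                "dataset_id", "mmp_or_pathway", "covariate", "per_tumour_r",
                "mean_pearson_r", "p_pearson_adj", "p_spearman_adj",
                "significant", "retained",
            ]
        )
    frame = pd.DataFrame(rows)
    frame["p_pearson_adj"] = multipletests(frame["p_pearson"], method="fdr_bh")[1]
    frame["p_spearman_adj"] = multipletests(frame["p_spearman"], method="fdr_bh")[1]
    frame["significant"] = (
        (frame["p_pearson_adj"] < 0.05)
        & (frame["p_spearman_adj"] < 0.05)
        & (frame["mean_pearson_r"].abs() > r_threshold)
    )
    frame["retained"] = frame["significant"]
    if top_k is not None:
        for (_, _), grp in frame.groupby(["dataset_id", "mmp_or_pathway"]):
            sig = grp[grp["significant"]]
            if len(sig) > top_k:
                drop = sig["mean_pearson_r"].abs().nsmallest(len(sig) - top_k).index
                frame.loc[drop, "retained"] = False
    frame = frame.drop(columns=["p_pearson", "p_spearman"])
    return frame.sort_values(
        ["dataset_id", "mmp_or_pathway", "covariate"], kind="mergesort"
    ).reset_index(drop=True)


def cooccurrence(
    scores: pd.DataFrame,
    cell_meta: pd.DataFrame,
    score_threshold: float = 0.5,
    p_cut: float = 1e-5,
    min_tumours: int = 5,
    minmax_normalize: bool = True,
) -> pd.DataFrame:
    """Positive-correlation network over per-tumour program-active fractions.

    ``scores`` holds per-cell program scores (NaN where a program does not
    apply to a cell's type); ``cell_meta`` supplies ``sample_id`` and
    ``dataset_id``.  Scores are min-max normalized per dataset (raw AUC-type
    scores rarely reach 0.5), the per-tumour fraction of cells above
    ``score_threshold`` is z-scaled within each dataset, and Pearson
    correlations across tumours keep only edges with r > 0 and p < ``p_cut``.
    """
    meta = cell_meta.loc[scores.index]
    work = scores.copy()
    if minmax_normalize:
        for ds in pd.unique(meta["dataset_id"]):
            mask = (meta["dataset_id"] == ds).to_numpy()
            block = work.loc[mask]
            lo, hi = block.min(), block.max()
            rng_span = (hi - lo).replace(0, np.nan)
            work.loc[mask] = (block - lo) / rng_span

    active = work > score_threshold
    frac = active.groupby(meta["sample_id"]).sum() / work.notna().groupby(meta["sample_id"]).sum()
    sample_ds = meta.groupby("sample_id")["dataset_id"].first()
    if len(frac) < min_tumours:
        raise ValueError(f"co-occurrence needs >= {min_tumours} tumours")
    scaled = frac.copy()
    for ds in pd.unique(sample_ds):
        rows = sample_ds.index[sample_ds == ds]
        block = frac.loc[rows]
        sd = block.std(ddof=0)
        scaled.loc[rows] = (block - block.mean()) / sd.replace(0, np.nan)

    cols = []
    for c in scaled.columns:
        v = scaled[c].dropna()
        if len(v) >= min_tumours and v.std(ddof=0) > 0:
            cols.append(c)
        else:
            logger.warning("program %s has zero variance across tumours; excluded", c)

    edges = []
    for i, ca in enumerate(cols):
        for cb in cols[i + 1 :]:
            pair = scaled[[ca, cb]].dropna()
            if len(pair) < min_tumours:
                continue
            r, p = scipy.stats.pearsonr(pair[ca], pair[cb])
            if r > 0 and p < p_cut:
                edges.append(
                    {"mmp_a": ca, "mmp_b": cb, "pearson_r": float(r), "p_value": float(p)}
                )
    return pd.DataFrame(edges, columns=["mmp_a", "mmp_b", "pearson_r", "p_value"])


def pve(
    scores: pd.Series,
    metrics: pd.DataFrame,
    min_individuals: int = 5,
) -> pd.DataFrame:
    """Proportion of variance in a score explained by each clinical metric.

    One linear model per metric (categoricals one-hot encoded); the adjusted
    R-squared is the PVE, significance is the model F-test with BH adjustment
    over metrics.  Constant metrics are skipped.
    """
    if len(scores) < min_individuals:
        raise ValueError(f"pve needs >= {min_individuals} individuals")
    rows = []
    for col in metrics.columns:
        m = metrics[col]
        joined = pd.concat([scores.rename("score"), m.rename("metric")], axis=1).dropna()
        if len(joined) < min_individuals or joined["metric"].nunique() < 2:
            logger.warning("metric %s constant or too sparse; skipped", col)
            continue
        if pd.api.types.is_numeric_dtype(joined["metric"]):
            design = joined[["metric"]].astype(float)
        else:
            design = pd.get_dummies(joined["metric"], drop_first=True, dtype=float)
        model = sm.OLS(joined["score"].astype(float), sm.add_constant(design)).fit()
        rows.append(
            {
                "metric": col,
                "pve": float(model.rsquared_adj),
                "p_value": float(model.f_pvalue),
                "n": int(len(joined)),
            }
        )
    frame = pd.DataFrame(rows, columns=["metric", "pve", "p_value", "n"])
    if not frame.empty:
        frame["p_adj"] = multipletests(frame["p_value"], method="fdr_bh")[1]
    else:
        frame["p_adj"] = []
    return frame


def fc_correlation(fc_a: pd.Series, fc_b: pd.Series, min_shared: int = 10) -> float:
    """Spearman correlation of two per-gene log2 fold-change vectors over the
    genes finite in both."""
    joined = pd.concat([fc_a.rename("a"), fc_b.rename("b")], axis=1, join="inner")
    joined = joined.replace([np.inf, -np.inf], np.nan).dropna()
    if len(joined) < min_shared:
        raise ValueError(f"fewer than {min_shared} shared finite genes")
    return float(scipy.stats.spearmanr(joined["a"], joined["b"]).statistic)
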