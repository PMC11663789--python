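"""Metabolic meta-program discovery.

Per-sample NMF over the scaled non-negative metabolic matrix (one
decomposition per K in the configured schedule, each factor summarized by its
top-30 coefficient genes), a three-criterion robustness filter, greedy
founder-extension clustering of robust programs into meta-programs (MMPs),
hypergeometric pathway annotation, and the per-cancer-type abundance
statistic with its stratification rules.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
import zlib
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning
from statsmodels.stats.multitest import multipletests

from metahet.io_core import CellExpression, GeneSet
from metahet import preprocess

logger = logging.getLogger(__name__)

DEFAULT_K_VALUES = (4, 5, 6, 7, 8, 9)
PROGRAM_SIZE = 30
#: "at least 70%" of 30 genes -> >= 21 shared genes (inclusive)
WITHIN_SAMPLE_MIN_OVERLAP = 21
#: "at least 20%" of 30 genes -> >= 6 shared genes (inclusive)
CROSS_TUMOUR_MIN_OVERLAP = 6
#: "more than 20%" of 30 genes -> >= 7 shared genes (strict)
REDUNDANCY_OVERLAP = 7
MIN_MEMBERS = 10
MIN_SIMILAR = 5
MIN_CELLS_PER_SAMPLE = 20


@dataclasses.dataclass
class NMFProgram:
    """One factor of a per-sample NMF, summarized by its top-30 genes."""

    sample_id: str
    k: int
    factor_index: int
    genes: list[str]
    coefficients: list[float]
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.genes) != PROGRAM_SIZE:
            raise ValueError(f"program must have exactly {PROGRAM_SIZE} genes")
        coeffs = np.asarray(self.coefficients, dtype=float)
        if np.any(np.diff(coeffs) > 1e-12):
            raise ValueError("coefficients must be sorted non-increasing")

    @property
    def program_id(self) -> str:
        return f"{self.sample_id}|K{self.k}|F{self.factor_index}"

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclasses.dataclass
class MMP:
    """A cluster of robust NMF programs with a consensus 30-gene list."""

    mmp_id: str
    genes: list[str]
    members: list[str]  # program ids
    member_programs: list[NMFProgram] = dataclasses.field(default_factory=list, repr=False)
    annotation: tuple[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.genes) != PROGRAM_SIZE:
            raise ValueError(f"MMP must have exactly {PROGRAM_SIZE} genes")

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def tumours(self) -> set:
        return {p.sample_id for p in self.member_programs}


@dataclasses.dataclass
class AbundanceRecord:
    cancer_type: str
    mmp_id: str
    observed: int
    expected: float
    abundance: float
    p_bonferroni: float
    category: str
    n_mmp_total: int
    n_cancer_total: int
    n_robust_total: int


def overlap(a: Iterable[str], b: Iterable[str]) -> int:
    """Number of shared genes between two program gene lists."""
    return len(frozenset(a) & frozenset(b))


# ---------------------------------------------------------------------------
# per-sample NMF
# ---------------------------------------------------------------------------


def _nmf_seed(seed: int, sample_id: str, k: int) -> int:
    return (seed + zlib.crc32(f"{sample_id}|{k}".encode())) % (2**31 - 1)


def nmf_programs(
    matrix: pd.DataFrame,
    sample_id: str,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    seed: int = 0,
    min_cells: int = MIN_CELLS_PER_SAMPLE,
) -> list[NMFProgram]:
    """Factorize one sample's scaled non-negative cells x genes matrix.

    One NMF per K (deterministic NNDSVD init, coordinate descent, Frobenius
    loss); each factor becomes a program of its 30 highest-coefficient genes,
    so a full K schedule yields ``sum(k_values)`` programs.  Samples below
    ``min_cells`` cells are skipped with a log entry; non-convergence is
    flagged on the emitted programs, not raised.
    """
    if matrix.shape[0] < min_cells:
        logger.info(
            "sample %s has %d cells (< %d); skipped", sample_id, matrix.shape[0], min_cells
        )
        return []
    if matrix.shape[1] < PROGRAM_SIZE:
        raise ValueError(f"sample {sample_id}: fewer than {PROGRAM_SIZE} genes")
    vals = matrix.to_numpy(dtype=float)
    if vals.min() < 0:
        raise ValueError("NMF input must be non-negative")
    genes = matrix.columns.to_numpy(dtype=object)
    programs: list[NMFProgram] = []
    for k in k_values:
        model = NMF(
            n_components=k,
            init="nndsvd",
            solver="cd",
            beta_loss="frobenius",
            max_iter=500,
            tol=1e-4,
            random_state=_nmf_seed(seed, sample_id, k),
        )
        converged = True
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                w = model.fit_transform(vals.T)  # genes x k
            except ConvergenceWarning:
                converged = False
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    w = model.fit_transform(vals.T)
        for j in range(k):
            col = w[:, j]
            order = sorted(range(len(genes)), key=lambda i: (-col[i], str(genes[i])))
            top = order[:PROGRAM_SIZE]
            programs.append(
                NMFProgram(
                    sample_id=sample_id,
                    k=k,
                    factor_index=j,
                    genes=[str(genes[i]) for i in top],
                    coefficients=[float(col[i]) for i in top],
                    converged=converged,
                )
            )
    return programs


# ---------------------------------------------------------------------------
# robustness filtering
# ---------------------------------------------------------------------------


def robust_filter(programs: Sequence[NMFProgram]) -> list[NMFProgram]:
    """Keep programs that are (1) robust within the sample, (2) robust across
    tumours and (3) non-redundant within the tumour.

    (1) >= 21/30 genes shared with a program of a *different* K in the same
    sample; (2) >= 6/30 genes shared with a program from another tumour;
    (3) per tumour, survivors are sorted descending by their max cross-tumour
    overlap and selected top-down, dropping any program sharing >= 7/30 genes
    with an already-selected one.
    """
    by_sample: dict[str, list[NMFProgram]] = {}
    for p in programs:
        by_sample.setdefault(p.sample_id, []).append(p)

    sets = {p.program_id: p.gene_set for p in programs}

    # criteria 1 & 2
    survivors: list[NMFProgram] = []
    for p in programs:
        same = by_sample[p.sample_id]
        c1 = any(
            q.k != p.k and len(sets[p.program_id] & sets[q.program_id]) >= WITHIN_SAMPLE_MIN_OVERLAP
            for q in same
        )
        if not c1:
            continue
        c2 = any(
            q.sample_id != p.sample_id
            and len(sets[p.program_id] & sets[q.program_id]) >= CROSS_TUMOUR_MIN_OVERLAP
            for q in programs
        )
        if c2:
            survivors.append(p)

    # criterion 3: within-tumour non-redundancy among survivors
    surv_by_sample: dict[str, list[NMFProgram]] = {}
    for p in survivors:
        surv_by_sample.setdefault(p.sample_id, []).append(p)
    result: list[NMFProgram] = []
    for sample_id, plist in surv_by_sample.items():
        others = [q for q in survivors if q.sample_id != sample_id]
        def max_cross(p: NMFProgram) -> int:
            return max((len(sets[p.program_id] & sets[q.program_id]) for q in others), default=0)
        ordered = sorted(plist, key=lambda p: (-max_cross(p), p.k, p.factor_index))
        selected: list[NMFProgram] = []
        for p in ordered:
            if all(
                len(sets[p.program_id] & sets[q.program_id]) < REDUNDANCY_OVERLAP
                for q in selected
            ):
                selected.append(p)
        result.extend(selected)
    # stable overall order: by sample, K, factor
    result.sort(key=lambda p: (p.sample_id, p.k, p.factor_index))
    return result


# ---------------------------------------------------------------------------
# clustering robust programs into MMPs
# ---------------------------------------------------------------------------


def _consensus_genes(members: list[NMFProgram]) -> list[str]:
    """Top-30 genes by occurrence across member programs.

    Ties break toward the higher summed within-program coefficient rank
    (position 0 in a member contributes 30, position 29 contributes 1), then
    lexicographic symbol order.
    """
    occurrence: dict[str, int] = {}
    rank_score: dict[str, int] = {}
    for p in members:
        for pos, g in enumerate(p.genes):
            occurrence[g] = occurrence.get(g, 0) + 1
            rank_score[g] = rank_score.get(g, 0) + (PROGRAM_SIZE - pos)
    ordered = sorted(occurrence, key=lambda g: (-occurrence[g], -rank_score[g], g))
    return ordered[:PROGRAM_SIZE]


def cluster_mmps(
    robust: Sequence[NMFProgram],
    min_overlap: float = 0.2,
    min_members: int = MIN_MEMBERS,
    min_similar: int = MIN_SIMILAR,
) -> tuple[list[MMP], list[NMFProgram]]:
    """Greedy founder-extension clustering of robust programs.

    Programs are sorted descending by their number of similar programs (> 20%
    gene overlap, necessarily from other tumours); the top program founds a
    cluster whose gene list it seeds.  The unclustered program with the
    highest overlap with the current consensus list is added repeatedly, the
    consensus being recomputed as the 30 most-occurring genes, until no
    program exceeds the overlap threshold.  New founders are attempted while
    some candidate still has at least ``min_similar`` similar programs.
    Clusters with fewer than ``min_members`` members (or spanning a single
    tumour) are discarded; their programs are returned as unassigned.
    """
    thr = int(np.floor(min_overlap * PROGRAM_SIZE)) + 1  # "more than" -> strict
    remaining = list(robust)
    clusters: list[list[NMFProgram]] = []
    cluster_genes: list[list[str]] = []

    def sort_key(p: NMFProgram):
        return (p.sample_id, p.k, p.factor_index)

    while remaining:
        sim_counts = {
            p.program_id: sum(
                1
                for q in remaining
                if q.sample_id != p.sample_id and overlap(p.genes, q.genes) >= thr
            )
            for p in remaining
        }
        founder = min(remaining, key=lambda p: (-sim_counts[p.program_id], sort_key(p)))
        if sim_counts[founder.program_id] < min_similar:
            break
        members = [founder]
        genes = list(founder.genes)
        remaining.remove(founder)
        while remaining:
            best = min(
                remaining, key=lambda p: (-overlap(p.genes, genes), sort_key(p))
            )
            if overlap(best.genes, genes) < thr:
                break
            members.append(best)
            remaining.remove(best)
            genes = _consensus_genes(members)
        clusters.append(members)
        cluster_genes.append(genes)

    mmps: list[MMP] = []
    unassigned = list(remaining)
    n = 0
    for members, genes in zip(clusters, cluster_genes):
        tumours = {p.sample_id for p in members}
        if len(members) < min_members or len(tumours) < 2:
            unassigned.extend(members)
            continue
        n += 1
        mmps.append(
            MMP(
                mmp_id=f"MMP{n}",
                genes=genes,
                members=[p.program_id for p in members],
                member_programs=members,
            )
        )
    unassigned.sort(key=sort_key)
    return mmps, unassigned


# ---------------------------------------------------------------------------
# annotation and abundance
# ---------------------------------------------------------------------------


def annotate_mmp(
    m: MMP, pathways: Sequence[GeneSet], background: Sequence[str]
) -> tuple[str, float]:
    """Hypergeometric enrichment of the consensus genes against pathways.

    Population = background gene universe; BH adjustment across pathways; the
    top pathway with adjusted p < 0.05 becomes the annotation, otherwise
    ``("unannotated", nan)``.  The result is also stored on ``m``.
    """
    if not pathways:
        raise ValueError("empty pathway collection")
    bg = frozenset(background)
    mmp_genes = frozenset(m.genes)
    if not mmp_genes <= bg:
        raise ValueError("background must contain all MMP genes")
    M = len(bg)
    N = len(mmp_genes)
    pvals = []
    for pw in pathways:
        pw_genes = frozenset(pw.genes) & bg
        k = len(mmp_genes & pw_genes)
        pvals.append(float(scipy.stats.hypergeom.sf(k - 1, M, len(pw_genes), N)))
    padj = multipletests(pvals, method="fdr_bh")[1]
    best = int(np.argmin(padj))
    if padj[best] < 0.05 and len(mmp_genes & frozenset(pathways[best].genes)) > 0:
        m.annotation = (pathways[best].name, float(padj[best]))
    else:
        m.annotation = ("unannotated", float("nan"))
    return m.annotation


ABUNDANCE_CATEGORIES = ("high_significant", "high", "medium", "low", "absent")


def _categorize(observed: int, abundance_value: float, p_adj: float) -> str:
    """Stratification rules evaluated in order high -> medium -> low -> absent."""
    if observed > 10 or abundance_value > 1:
        return "high_significant" if p_adj < 0.05 else "high"
    if 2 <= observed <= 10 or 0 < abundance_value <= 1:
        return "medium"
    if observed == 1 and -1.5 < abundance_value <= 0:
        return "low"
    return "absent"


def abundance(
    mmps: Sequence[MMP],
    program_cancer_types: Mapping[str, str],
) -> pd.DataFrame:
    """Observed vs expected member-program counts per (MMP, cancer type).

    ``program_cancer_types`` maps every robust program id to its cancer type
    (this defines N_robust and the per-type totals).  Expected count is
    ``N_MMP * N_cancer / N_robust``; abundance is
    ``log2((observed+1)/(expected+1))``; the upper-tail hypergeometric p
    (population N_robust, successes N_MMP, draws N_cancer) is Bonferroni
    adjusted over all (MMP, cancer type) pairs.
    """
    n_robust = len(program_cancer_types)
    if n_robust == 0:
        raise ValueError("no robust programs")
    type_counts = pd.Series(list(program_cancer_types.values())).value_counts()
    cancer_types = sorted(type_counts.index)
    n_tests = len(mmps) * len(cancer_types)
    rows = []
    for m in mmps:
        n_mmp = m.n_members
        member_types = [program_cancer_types[pid] for pid in m.members]
        for ct in cancer_types:
            n_cancer = int(type_counts[ct])
            observed = sum(1 for t in member_types if t == ct)
            expected = n_mmp * n_cancer / n_robust
            ab = float(np.log2((observed + 1) / (expected + 1)))
            p = float(scipy.stats.hypergeom.sf(observed - 1, n_robust, n_mmp, n_cancer))
            p_bonf = min(1.0, p * n_tests)
            rows.append(
                AbundanceRecord(
                    cancer_type=ct,
                    mmp_id=m.mmp_id,
                    observed=observed,
                    expected=expected,
                    abundance=ab,
                    p_bonferroni=p_bonf,
                    category=_categorize(observed, ab, p_bonf),
                    n_mmp_total=n_mmp,
                    n_cancer_total=n_cancer,
                    n_robust_total=n_robust,
                )
            )
    return pd.DataFrame([dataclasses.asdict(r) for r in rows]).sort_values(
        ["mmp_id", "cancer_type"], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


def per_sample_matrices(
    x: CellExpression,
    metabolic_genes: GeneSet,
    top_n_genes: int = 500,
    min_cells: int = MIN_CELLS_PER_SAMPLE,
) -> dict[str, pd.DataFrame]:
    """Per-sample preprocessing chain: normalize, select metabolic, scale+clip."""
    out: dict[str, pd.DataFrame] = {}
    for sample_id in pd.unique(x.cell_meta["sample_id"]):
        sub = x.subset_cells((x.cell_meta["sample_id"] == sample_id).to_numpy())
        if sub.n_cells < min_cells:
            logger.info("sample %s below %d cells; excluded", sample_id, min_cells)
            continue
        norm = preprocess.lognormalize(sub)
        reduced = preprocess.select_metabolic(norm, metabolic_genes, top_n=top_n_genes)
        out[sample_id] = preprocess.scale_and_clip(reduced)
    return out


def discover_mmps(
    x: CellExpression,
    metabolic_genes: GeneSet,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
    seed: int = 0,
    min_members: int = MIN_MEMBERS,
    min_similar: int = MIN_SIMILAR,
) -> tuple[list[NMFProgram], list[NMFProgram], list[MMP]]:
    """Full discovery chain on malignant cells: programs -> robust -> MMPs."""
    matrices = per_sample_matrices(x, metabolic_genes)
    programs: list[NMFProgram] = []
    for sample_id, mat in matrices.items():
        programs.extend(nmf_programs(mat, sample_id, k_values=k_values, seed=seed))
    robust = robust_filter(programs)
    mmps, _ = cluster_mmps(robust, min_members=min_members, min_similar=min_similar)
    return programs, robust, mmps


def jaccard_matrix(programs: Sequence[NMFProgram]) -> pd.DataFrame:
    """Pairwise Jaccard similarity of program gene lists (heatmap input)."""
    ids = [p.program_id for p in programs]
    sets = [p.gene_set for p in programs]
    n = len(sets)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            out[i, j] = out[j, i] = inter / (len(sets[i] | sets[j]))
    return pd.DataFrame(out, index=ids, columns=ids)
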