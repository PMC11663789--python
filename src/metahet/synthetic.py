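"""Synthetic multi-dataset tumour/normal scRNA-seq cohorts with planted truth.

Cohorts carry planted cell-type marker modules, malignant-cell CNV segments
and subpopulation-restricted coordinately upregulated metabolic gene modules,
plus the ground-truth tables needed to verify that each pipeline stage
recovers them.  Counts are negative binomial with a gene-shared dispersion;
all randomness flows from a single seeded generator so identical config+seed
gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from metahet.io_core import CellExpression

N_CHROMOSOMES = 22


class ConfigError(ValueError):
    """Synthetic configuration is internally inconsistent."""


@dataclasses.dataclass
class CellTypeSpec:
    name: str
    frequency: float
    n_marker_genes: int = 25
    marker_log2_effect: float = 3.0
    malignant_capable: bool = False


@dataclasses.dataclass
class ProgramSpec:
    """A planted metabolic gene module restricted to a cell subpopulation."""

    name: str
    genes: list[str]
    cell_type: str
    active_fraction: float
    log2_effect: float
    active_tumours: list[str]
    #: multiplicative per-tumour jitter of the active fraction, in [0, 1);
    #: decorrelates program strengths across tumours
    fraction_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.active_fraction < 1:
            raise ConfigError(f"{self.name}: active_fraction must be in (0,1)")
        if not 0 <= self.fraction_jitter < 1:
            raise ConfigError(f"{self.name}: fraction_jitter must be in [0,1)")


@dataclasses.dataclass
class CNVSegmentSpec:
    sample_id: str
    chromosome: str
    start: int
    end: int
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ConfigError("CNV factor must be > 0")


@dataclasses.dataclass
class SyntheticConfig:
    seed: int = 0
    n_datasets: int = 1
    tumour_samples_per_dataset: int = 4
    normal_samples_per_dataset: int = 2
    cells_per_sample: int = 200
    n_genes: int = 2000
    metabolic_fraction: float = 0.4
    cancer_types: tuple[str, ...] = ("BRCA", "CRC", "LUAD", "PAAD")
    cell_types: list[CellTypeSpec] = dataclasses.field(
        default_factory=lambda: [
            CellTypeSpec("Epithelial", 0.35, malignant_capable=True),
            CellTypeSpec("T_cell", 0.20),
            CellTypeSpec("B_cell", 0.10),
            CellTypeSpec("Myeloid", 0.15),
            CellTypeSpec("Fibroblast", 0.12),
            CellTypeSpec("Endothelial", 0.08),
        ]
    )
    malignant_fraction: float = 0.85
    programs: list[ProgramSpec] = dataclasses.field(default_factory=list)
    cnv_segments: list[CNVSegmentSpec] = dataclasses.field(default_factory=list)
    library_log_mean: float = np.log(2500.0)
    library_log_sd: float = 0.25
    n_mito_genes: int = 10
    mito_baseline_fraction: float = 0.05
    nb_dispersion: float = 10.0
    base_rate_log_sd: float = 0.8
    #: per-(sample, gene) multiplicative log-normal jitter of baseline rates;
    #: decorrelates background expression structure across samples
    sample_rate_log_sd: float = 0.0
    #: baseline log-rate distribution for planted program genes; a moderate
    #: positive mean and tighter spread keep module genes above the
    #: mean-expression selection cutoff in every tumour
    program_gene_rate_log_mean: float = 0.5
    program_gene_rate_log_sd: float = 0.4
    #: expression module upregulated in every malignant cell (DE effect on
    #: top of CNV); 0 disables
    n_malignant_marker_genes: int = 0
    malignant_marker_log2_effect: float = 2.0

    def __post_init__(self) -> None:
        freqs = np.array([ct.frequency for ct in self.cell_types], dtype=float)
        if freqs.min() <= 0 or abs(freqs.sum() - 1.0) > 1e-6:
            raise ConfigError("cell type frequencies must be positive and sum to 1")
        if not 0 < self.metabolic_fraction < 1:
            raise ConfigError("metabolic_fraction must be in (0,1)")
        if not 0 < self.malignant_fraction <= 1:
            raise ConfigError("malignant_fraction must be in (0,1]")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic cohort."""

    cells: pd.DataFrame  # indexed by cell_id: cell_type, malignant, ...
    program_activity: pd.DataFrame  # cells x program names (bool)
    cnv_segments: pd.DataFrame
    programs: dict[str, list[str]]
    metabolic_genes: list[str]
    marker_genes: dict[str, list[str]]


# ---------------------------------------------------------------------------
# gene universe
# ---------------------------------------------------------------------------


def gene_universe(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic gene table: symbols, metabolic/mito flags and positions.

    Genes are laid round-robin across 22 chromosomes in index order so every
    chromosome mixes metabolic, background and module genes.
    """
    n_met = int(round(config.n_genes * config.metabolic_fraction))
    n_mito = config.n_mito_genes
    n_bg = config.n_genes - n_met - n_mito
    if n_bg <= 0:
        raise ConfigError("n_genes too small for metabolic + mito genes")
    symbols = (
        [f"METG{i + 1:04d}" for i in range(n_met)]
        + [f"GENE{i + 1:04d}" for i in range(n_bg)]
        + [f"MT-G{i + 1:02d}" for i in range(n_mito)]
    )
    idx = np.arange(config.n_genes)
    chrom = np.array([f"chr{(i % N_CHROMOSOMES) + 1}" for i in idx], dtype=object)
    start = (idx // N_CHROMOSOMES + 1) * 100_000
    return pd.DataFrame(
        {
            "gene_symbol": symbols,
            "chromosome": chrom,
            "start": start,
            "metabolic": [s.startswith("METG") for s in symbols],
            "mito": [s.startswith("MT-") for s in symbols],
        }
    )


def metabolic_gene_symbols(config: SyntheticConfig) -> list[str]:
    n_met = int(round(config.n_genes * config.metabolic_fraction))
    return [f"METG{i + 1:04d}" for i in range(n_met)]


def _sample_ids(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for d in range(config.n_datasets):
        ds = f"DS{d + 1}"
        for t in range(config.tumour_samples_per_dataset):
            rows.append(
                {
                    "sample_id": f"{ds}_T{t + 1:02d}",
                    "dataset_id": ds,
                    "tissue": "tumour",
                    "cancer_type": config.cancer_types[t % len(config.cancer_types)],
                }
            )
        for n in range(config.normal_samples_per_dataset):
            rows.append(
                {
                    "sample_id": f"{ds}_N{n + 1:02d}",
                    "dataset_id": ds,
                    "tissue": "normal",
                    "cancer_type": config.cancer_types[n % len(config.cancer_types)],
                }
            )
    return pd.DataFrame(rows)


def tumour_sample_ids(config: SyntheticConfig) -> list[str]:
    tab = _sample_ids(config)
    return tab.loc[tab["tissue"] == "tumour", "sample_id"].tolist()


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SyntheticConfig) -> tuple[CellExpression, SyntheticTruth]:
    """Draw a cohort of NB counts with planted markers, programs and CNVs.

    Per-cell gene rates multiply in cell-type marker effects, program effects
    (only in active cells of the target type in active tumours) and CNV
    factors over segment genes of malignant cells; rates are normalized to
    probabilities and scaled by a log-normal library size.
    """
    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config)
    symbols = genes["gene_symbol"].to_numpy(dtype=object)
    sym_pos = {g: i for i, g in enumerate(symbols)}
    n_genes = len(symbols)

    # planted modules must reference known metabolic genes
    for prog in config.programs:
        unknown = [g for g in prog.genes if g not in sym_pos]
        if unknown:
            raise ConfigError(f"program {prog.name} references unknown genes: {unknown[:3]}")

    # marker modules: disjoint blocks of background genes
    bg_idx = np.flatnonzero(~genes["metabolic"] & ~genes["mito"])
    marker_genes: dict[str, list[str]] = {}
    cursor = 0
    for ct in config.cell_types:
        block = bg_idx[cursor : cursor + ct.n_marker_genes]
        if len(block) < ct.n_marker_genes:
            raise ConfigError("not enough background genes for marker modules")
        marker_genes[ct.name] = [symbols[i] for i in block]
        cursor += ct.n_marker_genes
    malignant_marker_idx = bg_idx[cursor : cursor + config.n_malignant_marker_genes]
    if len(malignant_marker_idx) < config.n_malignant_marker_genes:
        raise ConfigError("not enough background genes for malignant markers")
    if config.n_malignant_marker_genes:
        marker_genes["__malignant__"] = [symbols[i] for i in malignant_marker_idx]
    program_gene_set = {g for p in config.programs for g in p.genes}
    marker_gene_set = {g for gl in marker_genes.values() for g in gl}
    if program_gene_set & marker_gene_set:
        raise ConfigError("program modules overlap marker modules")

    # baseline rates; mitochondrial genes pinned to the configured fraction
    base = rng.lognormal(mean=0.0, sigma=config.base_rate_log_sd, size=n_genes)
    if program_gene_set:
        pg_idx = np.array(sorted(sym_pos[g] for g in program_gene_set), dtype=np.intp)
        base[pg_idx] = rng.lognormal(
            mean=config.program_gene_rate_log_mean,
            sigma=config.program_gene_rate_log_sd,
            size=len(pg_idx),
        )
    mito_idx = np.flatnonzero(genes["mito"])
    if len(mito_idx):
        non_mito_sum = base[~genes["mito"].to_numpy()].sum()
        target = config.mito_baseline_fraction / (1 - config.mito_baseline_fraction)
        base[mito_idx] *= target * non_mito_sum / base[mito_idx].sum()

    # CNV segment -> gene index list
    seg_genes: list[np.ndarray] = []
    for seg in config.cnv_segments:
        on_chrom = genes["chromosome"] == seg.chromosome
        in_span = (genes["start"] >= seg.start) & (genes["start"] <= seg.end)
        seg_genes.append(np.flatnonzero(on_chrom & in_span))

    samples = _sample_ids(config)
    ct_names = [ct.name for ct in config.cell_types]
    ct_freqs = np.array([ct.frequency for ct in config.cell_types])
    marker_idx = {
        ct.name: np.array([sym_pos[g] for g in marker_genes[ct.name]], dtype=np.intp)
        for ct in config.cell_types
    }
    marker_eff = {ct.name: 2.0 ** ct.marker_log2_effect for ct in config.cell_types}
    prog_idx = [np.array([sym_pos[g] for g in p.genes], dtype=np.intp) for p in config.programs]

    blocks: list[sp.csr_matrix] = []
    meta_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    activity_rows: list[np.ndarray] = []

    for srow in samples.itertuples(index=False):
        n = config.cells_per_sample
        cell_ids = [f"{srow.sample_id}_c{i + 1:04d}" for i in range(n)]
        types = rng.choice(len(ct_names), size=n, p=ct_freqs)
        is_tumour = srow.tissue == "tumour"
        malig_capable = np.array(
            [config.cell_types[t].malignant_capable for t in types]
        )
        malignant = (
            malig_capable & (rng.random(n) < config.malignant_fraction)
            if is_tumour
            else np.zeros(n, dtype=bool)
        )
        activity = np.zeros((n, len(config.programs)), dtype=bool)
        sample_base = base
        if config.sample_rate_log_sd > 0:
            sample_base = base * rng.lognormal(
                0.0, config.sample_rate_log_sd, size=n_genes
            )
        rates = np.tile(sample_base, (n, 1))
        for ci in range(n):
            ct = ct_names[types[ci]]
            rates[ci, marker_idx[ct]] *= marker_eff[ct]
        for pi, prog in enumerate(config.programs):
            if srow.sample_id not in prog.active_tumours:
                continue
            frac = prog.active_fraction
            if prog.fraction_jitter > 0:
                frac *= 1.0 + prog.fraction_jitter * (2.0 * rng.random() - 1.0)
            eligible = np.array([ct_names[t] == prog.cell_type for t in types])
            active = eligible & (rng.random(n) < frac)
            activity[:, pi] = active
            if active.any():
                rates[np.ix_(np.flatnonzero(active), prog_idx[pi])] *= 2.0 ** prog.log2_effect
        if malignant.any() and len(malignant_marker_idx):
            rates[np.ix_(np.flatnonzero(malignant), malignant_marker_idx)] *= (
                2.0 ** config.malignant_marker_log2_effect
            )
        for seg, gidx in zip(config.cnv_segments, seg_genes):
            if seg.sample_id == srow.sample_id and malignant.any() and len(gidx):
                rates[np.ix_(np.flatnonzero(malignant), gidx)] *= seg.factor

        probs = rates / rates.sum(axis=1, keepdims=True)
        libsize = rng.lognormal(config.library_log_mean, config.library_log_sd, size=n)
        mu = probs * libsize[:, None]
        lam = rng.gamma(shape=config.nb_dispersion, scale=mu / config.nb_dispersion)
        counts = rng.poisson(lam)
        blocks.append(sp.csr_matrix(counts))

        meta_rows.append(
            pd.DataFrame(
                {
                    "sample_id": srow.sample_id,
                    "dataset_id": srow.dataset_id,
                    "cancer_type": srow.cancer_type,
                    "tissue": srow.tissue,
                    "cell_type": [ct_names[t] for t in types],
                },
                index=pd.Index(cell_ids, name="cell_id"),
            )
        )
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample_id": srow.sample_id,
                    "dataset_id": srow.dataset_id,
                    "tissue": srow.tissue,
                    "cell_type": [ct_names[t] for t in types],
                    "malignant": malignant,
                },
                index=pd.Index(cell_ids, name="cell_id"),
            )
        )
        activity_rows.append(activity)

    cell_meta = pd.concat(meta_rows)
    x = CellExpression(
        counts=sp.vstack(blocks, format="csr"),
        gene_ids=symbols.copy(),
        gene_symbols=symbols.copy(),
        cell_meta=cell_meta,
        gene_positions=genes[["chromosome", "start"]].copy(),
    )
    truth = SyntheticTruth(
        cells=pd.concat(truth_rows),
        program_activity=pd.DataFrame(
            np.vstack(activity_rows) if config.programs else np.zeros((x.n_cells, 0), dtype=bool),
            index=cell_meta.index,
            columns=[p.name for p in config.programs],
        ),
        cnv_segments=pd.DataFrame(
            [dataclasses.asdict(s) for s in config.cnv_segments],
            columns=["sample_id", "chromosome", "start", "end", "factor"],
        ),
        programs={p.name: list(p.genes) for p in config.programs},
        metabolic_genes=metabolic_gene_symbols(config),
        marker_genes=marker_genes,
    )
    return x, truth


# ---------------------------------------------------------------------------
# default planted-program catalogue and cohort configs
# ---------------------------------------------------------------------------

DEFAULT_N_PROGRAMS = 15
MODULE_SIZE = 30


def default_program_catalogue(
    n_programs: int = DEFAULT_N_PROGRAMS,
    n_tumours: int = 36,
    tumours_per_program: int = 12,
    module_size: int = MODULE_SIZE,
    active_fraction_range: tuple[float, float] = (0.20, 0.30),
    log2_effect: float = 2.3,
    fraction_jitter: float = 0.2,
    cell_type: str = "Epithelial",
    tumour_ids: Sequence[str] | None = None,
) -> list[ProgramSpec]:
    """Disjoint planted metabolic modules, one per meta-program to recover.

    Each module has exactly ``module_size`` genes and is active in
    ``tumours_per_program`` tumours.  Active-tumour sets are assigned by a
    deterministic greedy load balancer so the per-tumour program load stays
    well within what a rank<=9 factorization can separate, and so no two
    modules share most of their active tumours.
    """
    if tumour_ids is None:
        tumour_ids = [f"DS1_T{i + 1:02d}" for i in range(n_tumours)]
    tumour_ids = list(tumour_ids)
    n_tumours = len(tumour_ids)
    if tumours_per_program > n_tumours:
        raise ConfigError("tumours_per_program exceeds available tumours")
    lo, hi = active_fraction_range
    load = {t: 0 for t in tumour_ids}
    programs = []
    for i in range(n_programs):
        genes = [f"METG{j + 1:04d}" for j in range(i * module_size, (i + 1) * module_size)]
        # least-loaded tumours first; rotate the tie-break with the program
        # index so equally loaded tumours are picked in a staggered order
        rotation = {t: (j - 7 * i) % n_tumours for j, t in enumerate(tumour_ids)}
        active = sorted(tumour_ids, key=lambda t: (load[t], rotation[t]))[:tumours_per_program]
        for t in active:
            load[t] += 1
        frac = lo if n_programs == 1 else lo + (hi - lo) * i / (n_programs - 1)
        programs.append(
            ProgramSpec(
                name=f"module{i + 1:02d}",
                genes=genes,
                cell_type=cell_type,
                active_fraction=frac,
                log2_effect=log2_effect,
                active_tumours=sorted(active),
                fraction_jitter=fraction_jitter,
            )
        )
    return programs


def default_mmp_config(seed: int = 0, n_tumours: int = 36, cells_per_sample: int = 320) -> SyntheticConfig:
    """Cohort used for meta-program discovery: malignant epithelium only.

    The planted catalogue requires each module's genes to survive the
    per-sample top-500 metabolic selection, so modules sit on 450 of the 800
    metabolic genes.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_datasets=1,
        tumour_samples_per_dataset=n_tumours,
        normal_samples_per_dataset=0,
        cells_per_sample=cells_per_sample,
        n_genes=2000,
        metabolic_fraction=0.4,
        cell_types=[CellTypeSpec("Epithelial", 1.0, malignant_capable=True)],
        malignant_fraction=1.0,
        nb_dispersion=10.0,
        sample_rate_log_sd=0.15,
    )
    cfg.programs = default_program_catalogue(tumour_ids=tumour_sample_ids(cfg))
    return cfg


def default_malignancy_config(seed: int = 0) -> SyntheticConfig:
    """Tumour+normal cohort with planted CNV gains/losses for malignancy calls."""
    cfg = SyntheticConfig(
        seed=seed,
        n_datasets=1,
        tumour_samples_per_dataset=4,
        normal_samples_per_dataset=3,
        cells_per_sample=300,
        n_genes=2000,
        metabolic_fraction=0.4,
        n_malignant_marker_genes=30,
        malignant_marker_log2_effect=2.0,
    )
    # recurrent core gains/losses shared by all tumours plus one private
    # segment each, mimicking recurrent arm-level events
    segments = []
    for t, private in zip(
        tumour_sample_ids(cfg), ("chr13", "chr17", "chr20", "chr21")
    ):
        segments.append(CNVSegmentSpec(t, "chr1", 1, 10_000_000, 2.0))
        segments.append(CNVSegmentSpec(t, "chr7", 1, 10_000_000, 2.0))
        segments.append(CNVSegmentSpec(t, "chr8", 1, 10_000_000, 0.5))
        segments.append(CNVSegmentSpec(t, private, 1, 10_000_000, 2.0))
    cfg.cnv_segments = segments
    return cfg
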