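"""Data model and readers/writers for the standard formats the pipeline touches.

Counts travel as a sparse cells x genes matrix bundled with per-cell metadata
(:class:`CellExpression`); gene sets come from GMT files; tabular results are
written with deterministic ordering so regression tests are bit-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

TISSUES = ("tumour", "normal")
MALIGNANCY = ("malignant", "non_malignant", "unassigned")
GENE_SET_CATEGORIES = ("pathway", "regulon", "hallmark", "signature", "mmp")

#: fixed float precision for all tabular output
FLOAT_FORMAT = "%.10g"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class IntegrityError(ValueError):
    """Input violates a data-model invariant (e.g. duplicate identifiers)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CellExpression:
    """Sparse cell x gene counts with per-cell annotations.

    Parameters
    ----------
    counts:
        Non-negative integer matrix, cells x genes (CSR).
    gene_ids, gene_symbols:
        Per-gene identifiers; ``gene_ids`` must be unique.
    cell_meta:
        DataFrame indexed by unique ``cell_id`` with at least ``sample_id``
        and ``dataset_id`` columns; optionally ``cancer_type``, ``tissue``,
        ``cell_type`` and ``malignancy``.
    gene_positions:
        Optional DataFrame aligned to genes with columns ``chromosome`` and
        ``start`` (1-based).  Rows may be NA for unpositioned genes.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    cell_meta: pd.DataFrame
    gene_positions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_symbols) != n_genes:
            raise FormatError(
                f"gene annotation length mismatch: matrix has {n_genes} genes, "
                f"{len(self.gene_ids)} ids / {len(self.gene_symbols)} symbols"
            )
        if len(self.cell_meta) != n_cells:
            raise FormatError(
                f"cell metadata length mismatch: matrix has {n_cells} cells, "
                f"meta has {len(self.cell_meta)} rows"
            )
        if self.cell_meta.index.has_duplicates:
            dup = self.cell_meta.index[self.cell_meta.index.duplicated()][:3]
            raise IntegrityError(f"duplicate cell ids: {list(dup)}")
        if pd.Index(self.gene_ids).has_duplicates:
            raise IntegrityError("duplicate gene ids")
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.floor(data))):
            raise IntegrityError("counts must be non-negative integers")
        for col in ("sample_id", "dataset_id"):
            if col not in self.cell_meta.columns:
                raise IntegrityError(f"cell_meta missing required column {col!r}")
            if self.cell_meta[col].isna().any():
                raise IntegrityError(f"cell_meta column {col!r} has missing values")
        if "tissue" in self.cell_meta.columns:
            bad = set(self.cell_meta["tissue"].dropna()) - set(TISSUES)
            if bad:
                raise IntegrityError(f"invalid tissue values: {sorted(bad)}")
        if "malignancy" in self.cell_meta.columns:
            bad = set(self.cell_meta["malignancy"].dropna()) - set(MALIGNANCY)
            if bad:
                raise IntegrityError(f"invalid malignancy values: {sorted(bad)}")
        if self.gene_positions is not None and len(self.gene_positions) != n_genes:
            raise FormatError("gene_positions length mismatch")

    # -- convenience --------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def subset_cells(self, mask_or_ids) -> "CellExpression":
        """Return a copy restricted to the given boolean mask or cell ids."""
        if isinstance(mask_or_ids, (pd.Series, np.ndarray)) and np.asarray(
            mask_or_ids
        ).dtype == bool:
            idx = np.flatnonzero(np.asarray(mask_or_ids))
        else:
            idx = self.cell_meta.index.get_indexer(pd.Index(mask_or_ids))
            if (idx < 0).any():
                raise KeyError("unknown cell ids in subset request")
        return CellExpression(
            counts=self.counts[idx],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
            cell_meta=self.cell_meta.iloc[idx].copy(),
            gene_positions=self.gene_positions,
        )

    def subset_genes(self, mask: np.ndarray) -> "CellExpression":
        idx = np.flatnonzero(np.asarray(mask))
        pos = self.gene_positions.iloc[idx].reset_index(drop=True) if self.gene_positions is not None else None
        return CellExpression(
            counts=self.counts[:, idx],
            gene_ids=self.gene_ids[idx],
            gene_symbols=self.gene_symbols[idx],
            cell_meta=self.cell_meta.copy(),
            gene_positions=pos,
        )


@dataclasses.dataclass
class GeneSet:
    """A named gene list with a category and (for regulons) its regulator."""

    name: str
    genes: list[str]
    category: str = "pathway"
    regulator: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise IntegrityError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise IntegrityError(f"gene set {self.name!r} has duplicate genes")
        if self.category not in GENE_SET_CATEGORIES:
            raise IntegrityError(
                f"gene set {self.name!r}: invalid category {self.category!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)


@dataclasses.dataclass
class ScoreMatrix:
    """Real-valued unit x gene-set score table (units are cells or samples)."""

    values: pd.DataFrame  # units x sets

    def __post_init__(self) -> None:
        if self.values.index.hasnans or self.values.columns.hasnans:
            raise IntegrityError("score matrix has missing unit/set labels")

    @property
    def units(self) -> pd.Index:
        return self.values.index

    @property
    def sets(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# counts I/O (Matrix Market, 10x dialect: genes are rows, cells are columns)
# ---------------------------------------------------------------------------


def read_counts(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    meta_path: str | Path,
) -> CellExpression:
    """Read a 10x-style MTX triplet plus a per-cell metadata TSV.

    Cells absent from the metadata table are dropped (logged); a metadata
    table indexed by ``cell_id`` is joined onto the barcodes.
    """
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except ValueError as exc:
        raise FormatError(f"invalid MTX file {matrix_path}: {exc}") from exc
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)[0]
    n_genes, n_cells = mat.shape
    if len(feats) != n_genes:
        raise FormatError(
            f"features file has {len(feats)} rows but matrix has {n_genes} gene rows"
        )
    if len(barcodes) != n_cells:
        raise FormatError(
            f"barcodes file has {len(barcodes)} rows but matrix has {n_cells} cell columns"
        )
    if barcodes.duplicated().any():
        raise IntegrityError("duplicate barcodes in barcodes file")
    gene_ids = feats[0].to_numpy(dtype=object)
    # features TSV may be 1, 2 or 3 columns: id / id+symbol / id+symbol+type
    gene_symbols = (
        feats[1].to_numpy(dtype=object) if feats.shape[1] >= 2 else gene_ids.copy()
    )
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise FormatError("metadata TSV must have a cell_id column")
    if meta["cell_id"].duplicated().any():
        raise IntegrityError("duplicate cell_id in metadata")
    meta = meta.set_index("cell_id")

    counts = sp.csr_matrix(mat.T)
    keep = barcodes.isin(meta.index).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("read_counts: dropped %d cells absent from metadata", n_dropped)
    counts = counts[np.flatnonzero(keep)]
    kept_barcodes = barcodes[keep]
    cell_meta = meta.loc[kept_barcodes].copy()
    return CellExpression(
        counts=counts, gene_ids=gene_ids, gene_symbols=gene_symbols, cell_meta=cell_meta
    )


def write_counts(x: CellExpression, out_dir: str | Path) -> None:
    """Write ``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv`` + ``meta.tsv``.

    The matrix is written genes x cells in canonical (column-major) entry
    order so two writes of the same data are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.csc_matrix(x.counts.T.astype(np.int64))
    mat.sum_duplicates()
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer", symmetry="general")
    pd.DataFrame({"id": x.gene_ids, "symbol": x.gene_symbols}).to_csv(
        out / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(x.cell_meta.index).to_csv(
        out / "barcodes.tsv", sep="\t", header=False, index=False
    )
    x.cell_meta.rename_axis("cell_id").reset_index().to_csv(
        out / "meta.tsv", sep="\t", index=False
    )
    if x.gene_positions is not None:
        pos = x.gene_positions.copy()
        pos.insert(0, "gene_symbol", x.gene_symbols)
        pos.dropna(subset=["chromosome"]).to_csv(
            out / "gene_positions.tsv", sep="\t", index=False
        )


def read_gene_positions(path: str | Path, gene_symbols: Sequence[str]) -> pd.DataFrame:
    """Read a (gene_symbol, chrom, start) TSV and align it to ``gene_symbols``.

    Genes missing from the table get NA rows.
    """
    tab = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in tab.columns}
    sym = cols.get("gene_symbol") or cols.get("symbol")
    chrom = cols.get("chrom") or cols.get("chromosome")
    start = cols.get("start")
    if not (sym and chrom and start):
        raise FormatError("gene position TSV needs gene_symbol, chrom, start columns")
    tab = tab.rename(columns={sym: "gene_symbol", chrom: "chromosome", start: "start"})
    tab = tab.drop_duplicates("gene_symbol").set_index("gene_symbol")
    aligned = tab.reindex(pd.Index(gene_symbols))[["chromosome", "start"]]
    return aligned.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(
    gmt_path: str | Path, min_regulon_targets: int = 5
) -> list[GeneSet]:
    """Parse a GMT file into :class:`GeneSet` objects.

    The GMT description field encodes the category, optionally with a
    regulator as ``regulon:TF``; unknown descriptions default to ``pathway``.
    Regulon sets with fewer than ``min_regulon_targets`` genes are dropped.
    """
    sets: list[GeneSet] = []
    with open(gmt_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{gmt_path}:{lineno}: GMT lines need >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            if not genes:
                logger.warning("skipping empty gene set %r", name)
                continue
            genes = list(dict.fromkeys(genes))  # dedupe, keep order
            category, regulator = "pathway", None
            token = desc.split(":", 1)
            if token[0] in GENE_SET_CATEGORIES:
                category = token[0]
                if category == "regulon":
                    regulator = token[1] if len(token) > 1 else name
            if category == "regulon" and len(genes) < min_regulon_targets:
                logger.info(
                    "dropping regulon %r with %d targets (< %d)",
                    name,
                    len(genes),
                    min_regulon_targets,
                )
                continue
            sets.append(GeneSet(name=name, genes=genes, category=category, regulator=regulator))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = s.category if s.regulator is None else f"{s.category}:{s.regulator}"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


def match_gene_sets(
    sets: Iterable[GeneSet], symbols: Sequence[str]
) -> dict[str, np.ndarray]:
    """Map set names to column indices present in ``symbols`` (case-sensitive).

    Unmatched set genes are ignored; the total is logged once.
    """
    pos = {g: i for i, g in enumerate(symbols)}
    out: dict[str, np.ndarray] = {}
    n_unmatched = 0
    for s in sets:
        idx = [pos[g] for g in s.genes if g in pos]
        n_unmatched += len(s.genes) - len(idx)
        out[s.name] = np.asarray(idx, dtype=np.intp)
    if n_unmatched:
        logger.info("match_gene_sets: %d set genes not found in matrix", n_unmatched)
    return out


# ---------------------------------------------------------------------------
# deterministic tables
# ---------------------------------------------------------------------------


def _to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    rows = []
    for r in records:
        if dataclasses.is_dataclass(r):
            rows.append(dataclasses.asdict(r))
        elif isinstance(r, Mapping):
            rows.append(dict(r))
        else:
            raise TypeError(f"unsupported record type {type(r).__name__}")
    return pd.DataFrame(rows)


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records as TSV or JSON with deterministic ordering.

    Rows are sorted by all columns (primary key first); floats use
    :data:`FLOAT_FORMAT`.  An empty record list with explicit ``columns``
    yields a header-only file.
    """
    path = Path(path)
    frame = _to_frame(records)
    if frame.empty and columns is not None:
        frame = pd.DataFrame(columns=list(columns))
    if not frame.empty:
        sort_cols = [c for c in frame.columns if frame[c].map(np.isscalar).all()]
        if sort_cols:
            frame = frame.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    if path.suffix == ".json":
        def _clean(v):
            if isinstance(v, (np.floating, float)):
                return float(f"{v:.10g}") if np.isfinite(v) else None
            if isinstance(v, np.integer):
                return int(v)
            if isinstance(v, np.bool_):
                return bool(v)
            if isinstance(v, (list, tuple, np.ndarray)):
                return [_clean(x) for x in v]
            return v
        payload = [
            {k: _clean(v) for k, v in row.items()}
            for row in frame.to_dict(orient="records")
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    return pd.read_csv(path, sep="\t")
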