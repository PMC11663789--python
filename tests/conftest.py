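import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from metahet.io_core import CellExpression, GeneSet
from metahet import synthetic as syn


def make_cells(
    counts,
    gene_symbols=None,
    sample_ids=None,
    dataset_ids=None,
    tissue=None,
    cell_type=None,
    cancer_type=None,
    gene_positions=None,
    cell_ids=None,
):
    """Build a CellExpression from a dense array with minimal metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if gene_symbols is None:
        gene_symbols = [f"G{i + 1:03d}" for i in range(n_genes)]
    if cell_ids is None:
        cell_ids = [f"c{i + 1:03d}" for i in range(n_cells)]
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids if sample_ids is not None else ["S1"] * n_cells,
            "dataset_id": dataset_ids if dataset_ids is not None else ["D1"] * n_cells,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if tissue is not None:
        meta["tissue"] = tissue
    if cell_type is not None:
        meta["cell_type"] = cell_type
    if cancer_type is not None:
        meta["cancer_type"] = cancer_type
    return CellExpression(
        counts=sp.csr_matrix(counts),
        gene_ids=np.asarray(gene_symbols, dtype=object),
        gene_symbols=np.asarray(gene_symbols, dtype=object),
        cell_meta=meta,
        gene_positions=gene_positions,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Small multi-sample tumour/normal cohort with all six lineages."""
    cfg = syn.SyntheticConfig(
        seed=11,
        tumour_samples_per_dataset=3,
        normal_samples_per_dataset=2,
        cells_per_sample=120,
        n_genes=800,
        metabolic_fraction=0.4,
    )
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def malignancy_cohort():
    cfg = syn.default_malignancy_config(seed=5)
    return syn.generate_cohort(cfg)


@pytest.fixture
def metabolic_set(small_cohort):
    _, truth = small_cohort
    return GeneSet("metabolic", truth.metabolic_genes)
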