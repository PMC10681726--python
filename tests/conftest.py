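import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from chromstress import CellExperiment


def build_experiment(gene_counts, hto_counts, gene_ids=None, hto_ids=None, mito_mask=None):
    """Construct a CellExperiment from dense arrays with generated ids."""
    gene_counts = np.atleast_2d(np.asarray(gene_counts))
    hto_counts = np.atleast_2d(np.asarray(hto_counts))
    n_cells, n_genes = gene_counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if hto_ids is None:
        hto_ids = [f"HTO{i + 1}" for i in range(hto_counts.shape[1])]
    if mito_mask is None:
        mito_mask = np.zeros(n_genes, dtype=bool)
    return CellExperiment(
        gene_counts=sparse.csr_matrix(gene_counts),
        hto_counts=hto_counts,
        gene_ids=list(gene_ids),
        hto_ids=list(hto_ids),
        barcode_ids=[f"bc{i}" for i in range(n_cells)],
        mito_mask=mito_mask,
    )


def qc_cell(umi, genes_detected, mito_frac, n_genes=9000, n_mito=100):
    """One cell's count vector hitting exact QC metrics (gene 0.. mito)."""
    row = np.zeros(n_genes, dtype=np.int64)
    mito = int(round(umi * mito_frac))
    ordinary_total = umi - mito
    n_ordinary = genes_detected - (1 if mito > 0 else 0)
    base = ordinary_total // n_ordinary
    row[n_mito : n_mito + n_ordinary] = base
    row[n_mito] += ordinary_total - base * n_ordinary
    if mito > 0:
        row[0] = mito
    assert row.sum() == umi and (row > 0).sum() == genes_detected
    return row


@pytest.fixture
def qc_universe():
    """Factory assembling an experiment from qc_cell vectors (first 100 genes mito)."""

    def make(cells):
        matrix = np.vstack(cells)
        n_genes = matrix.shape[1]
        mito_mask = np.zeros(n_genes, dtype=bool)
        mito_mask[:100] = True
        hto = np.zeros((matrix.shape[0], 2), dtype=np.int64)
        return build_experiment(matrix, hto, mito_mask=mito_mask)

    return make
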