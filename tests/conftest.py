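import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from crossbulk import CellCountMatrix, PseudobulkMatrix


def make_cells(counts, gene_ids=None, **meta_overrides):
    """Build a CellCountMatrix from a dense genes x cells array with simple metadata."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    meta = {
        "cell_id": [f"c{j}" for j in range(n_cells)],
        "sample_id": ["S1"] * n_cells,
        "study_id": ["study1"] * n_cells,
        "disease_state": ["control"] * n_cells,
        "cell_type": ["AT2"] * n_cells,
        "compartment": ["epithelial"] * n_cells,
        "chemistry": ["3'V2"] * n_cells,
        "seq_method": ["scRNA"] * n_cells,
    }
    meta.update(meta_overrides)
    return CellCountMatrix(
        counts=sp.csr_matrix(counts), gene_ids=np.array(gene_ids, dtype=object),
        cell_meta=pd.DataFrame(meta),
    )


def make_pb(counts, gene_ids=None, sample_ids=None, study_ids=None,
            disease_states=None, cell_types=None, n_cells=None):
    counts = np.asarray(counts)
    n_genes, n_units = counts.shape
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    meta = pd.DataFrame({
        "sample_id": sample_ids or [f"S{j}" for j in range(n_units)],
        "study_id": study_ids or ["study1"] * n_units,
        "disease_state": disease_states or ["control"] * n_units,
        "cell_type": cell_types or ["AT2"] * n_units,
        "n_cells": n_cells or [100] * n_units,
    })
    return PseudobulkMatrix(counts, np.array(gene_ids, dtype=object), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
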