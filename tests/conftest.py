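import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from umikit import CountMatrix, SimConfig, generate_cohort


def make_counts(array, genes=None, cells=None, batch=None) -> CountMatrix:
    """CountMatrix from a dense genes x cells array with default ids."""
    X = np.asarray(array)
    n_genes, n_cells = X.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    cells = cells or [f"C{j}" for j in range(n_cells)]
    batch = batch if batch is not None else ["B0"] * n_cells
    return CountMatrix(pd.Index(genes), pd.Index(cells), sp.csr_matrix(X), pd.Series(batch))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact multi-batch cohort with hemoglobin-high cells and doublets."""
    cfg = SimConfig(
        n_batches=2, cells_per_batch=300, n_genes=600, n_cell_types=5,
        doublet_fraction=0.04, seed=7,
    )
    matrix, truth = generate_cohort(cfg)
    return cfg, matrix, truth
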