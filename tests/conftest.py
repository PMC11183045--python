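import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dcmregnet import CellMatrix


def make_cell_matrix(counts: np.ndarray, gene_ids=None, cell_ids=None,
                     groups=None, batches=None, layer_tag="counts"):
    """Build a CellMatrix from a dense genes x cells array."""
    n_genes, n_cells = counts.shape
    gene_ids = gene_ids or [f"g{i:04d}" for i in range(n_genes)]
    cell_ids = cell_ids or [f"c{i:04d}" for i in range(n_cells)]
    groups = groups if groups is not None else ["Normal"] * n_cells
    batches = batches if batches is not None else ["b0"] * n_cells
    meta = pd.DataFrame({"sample_id": batches, "group": groups,
                         "batch": batches},
                        index=pd.Index(cell_ids, name="cell_id"))
    values = sp.csr_matrix(counts) if layer_tag == "counts" else counts
    return CellMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids,
                      cell_meta=meta, layer_tag=layer_tag)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_truth():
    from dcmregnet import simulate_truth
    return simulate_truth(n_celltypes=4, n_genes=400, n_tfs=8,
                          targets_per_tf=12, n_responsive=2,
                          markers_per_type=10, shared_pool_size=12,
                          seed=7)


@pytest.fixture(scope="session")
def small_cells(small_truth):
    from dcmregnet import simulate_single_cell
    cells, activities = simulate_single_cell(small_truth,
                                             n_cells_per_group=250,
                                             n_samples_per_group=2, seed=8)
    return cells, activities
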