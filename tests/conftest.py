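import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from myotrace.datasets import CellDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell_dataset(counts, sample_ids=None, saturations=None, gene_ids=None,
                      is_mito=None, is_ribo=None, **cell_cols):
    """Small hand-rolled CellDataset for unit tests."""
    counts = sparse.csr_matrix(np.asarray(counts))
    n_cells, n_genes = counts.shape
    if sample_ids is None:
        sample_ids = ["s0"] * n_cells
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n_genes)]
    if is_mito is None:
        is_mito = [False] * n_genes
    if is_ribo is None:
        is_ribo = [False] * n_genes
    uniq = list(dict.fromkeys(sample_ids))
    if saturations is None:
        saturations = {s: 1.0 for s in uniq}
    cell_meta = pd.DataFrame({"cell_id": [f"c{i}" for i in range(n_cells)],
                              "sample_id": sample_ids, **cell_cols})
    gene_meta = pd.DataFrame({"gene_id": gene_ids, "is_mito": is_mito, "is_ribo": is_ribo})
    sample_meta = pd.DataFrame({"sample_id": uniq,
                                "sequencing_saturation": [saturations[s] for s in uniq]})
    return CellDataset(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta,
                       sample_meta=sample_meta)


@pytest.fixture
def small_sim():
    """A small but realistic simulated dataset shared across tests."""
    from myotrace.simulate import SimConfig, generate_cells

    cfg = SimConfig(n_samples=3, cells_per_sample=300, n_genes=400,
                    intermediate_fraction=0.2, seed=77)
    return generate_cells(cfg)
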