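import numpy as np
import pytest
import scipy.sparse as sp

from xegmap.containers import CountMatrix, NormalizedMatrix
from xegmap.sim import SimConfig


def make_counts(arr, gene_prefix="g", cell_prefix="c") -> CountMatrix:
    arr = np.asarray(arr)
    genes = np.array([f"{gene_prefix}{i}" for i in range(arr.shape[0])], dtype=object)
    cells = np.array([f"{cell_prefix}{j}" for j in range(arr.shape[1])], dtype=object)
    return CountMatrix(sp.csc_matrix(arr), genes, cells)


def make_nm(arr, size_factors=None) -> NormalizedMatrix:
    """Wrap a dense array as already-normalized expression (unit size factors)."""
    arr = np.asarray(arr, dtype=float)
    genes = np.array([f"g{i}" for i in range(arr.shape[0])], dtype=object)
    cells = np.array([f"c{j}" for j in range(arr.shape[1])], dtype=object)
    sf = np.ones(arr.shape[1]) if size_factors is None else np.asarray(size_factors)
    return NormalizedMatrix(sp.csc_matrix(arr), genes, cells, sf)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_genes=300, n_atlas_cells=500, n_query_cells_per_sample=150, seed=7
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
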