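import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from tmedyn.containers import CountMatrix


def make_counts(counts: np.ndarray, mito_rows=(), meta: pd.DataFrame | None = None) -> CountMatrix:
    """CountMatrix from a dense genes x cells array; rows in
    ``mito_rows`` get the mitochondrial id prefix."""
    counts = np.asarray(counts)
    genes = np.array(
        [f"mt-g{i:03d}" if i in set(mito_rows) else f"g{i:03d}" for i in range(counts.shape[0])],
        dtype=object,
    )
    cells = np.array([f"c{j:03d}" for j in range(counts.shape[1])], dtype=object)
    return CountMatrix(sp.csr_matrix(counts), genes, cells, meta)


@pytest.fixture
def regular_tetrahedron() -> np.ndarray:
    """A well-conditioned 4-vertex simplex in 3D."""
    return np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float) * 2.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
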