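import numpy as np
import pytest
import scipy.sparse as sp

from tadremodel import ContactMatrix
from tadremodel.genome import BinTable


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_bins():
    return BinTable.from_uniform({"chr1": 60_000}, 1000)


def dense_to_matrix(a: np.ndarray, resolution: int = 1000,
                    chrom: str = "chr1", weights=None) -> ContactMatrix:
    """Wrap a symmetric dense array as a ContactMatrix."""
    n = a.shape[0]
    bt = BinTable.from_uniform({chrom: n * resolution}, resolution)
    m = ContactMatrix(bt, sp.csr_matrix(np.triu(a)))
    if weights is not None:
        m = m.with_weights(np.asarray(weights, dtype=float))
    return m


@pytest.fixture
def decay_matrix(rng):
    """Translation-invariant Poisson decay matrix with unit weights."""
    n = 80
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    lam = 2000.0 / (1 + d)
    a = rng.poisson(lam)
    a = np.triu(a) + np.triu(a, 1).T
    return dense_to_matrix(a.astype(float), weights=np.ones(n))
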