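import numpy as np
import pytest

from hpfactor.core import HyperParams, SparseCountMatrix, VariationalState


def random_count_matrix(rng, n_cells, n_genes, density=0.4, max_count=8):
    """Small random sparse count matrix for unit tests."""
    dense = rng.integers(1, max_count + 1, size=(n_cells, n_genes))
    dense *= rng.random((n_cells, n_genes)) < density
    # guarantee at least one non-zero
    if dense.sum() == 0:
        dense[0, 0] = 1
    return SparseCountMatrix.from_dense(dense)


def random_state(rng, n_cells, n_genes, K, hyper=None):
    """Random positive variational state with the fixed capacity shapes."""
    if hyper is None:
        hyper = HyperParams(K=K, b_prime=1.0, d_prime=1.0)
    pos = lambda shape: rng.uniform(0.2, 3.0, size=shape)
    return VariationalState(
        gamma_shape=pos((n_cells, K)),
        gamma_rate=pos((n_cells, K)),
        lambda_shape=pos((n_genes, K)),
        lambda_rate=pos((n_genes, K)),
        kappa_shape=np.full(n_cells, hyper.a_prime + K * hyper.a),
        kappa_rate=pos(n_cells),
        tau_shape=np.full(n_genes, hyper.c_prime + K * hyper.c),
        tau_rate=pos(n_genes),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    return random_count_matrix(rng, n_cells=6, n_genes=8)


@pytest.fixture
def small_hyper():
    return HyperParams(K=3, b_prime=0.8, d_prime=1.2)
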