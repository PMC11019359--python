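import numpy as np
import pytest

from transpco import (GeneCorrelationMatrix, calibrate_omnibus, eigendecompose,
                      make_block_sigma)


def equicorr(K: int, rho: float) -> GeneCorrelationMatrix:
    S = np.full((K, K), rho)
    np.fill_diagonal(S, 1.0)
    return GeneCorrelationMatrix(tuple(f"g{i + 1}" for i in range(K)), S)


@pytest.fixture(scope="session")
def model_k5():
    """Equicorrelated 5-gene model (rho = 0.5), shared across tests."""
    return eigendecompose(equicorr(5, 0.5))


@pytest.fixture(scope="session")
def calib_k5(model_k5):
    return calibrate_omnibus(model_k5, draws=100_000, seed=11)


@pytest.fixture(scope="session")
def blocks101():
    """Five-block 101-gene module correlation (rho = 0.7 within blocks)."""
    return make_block_sigma([20, 20, 20, 20, 21], rho_within=0.7)
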