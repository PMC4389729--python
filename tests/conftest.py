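import numpy as np
import pytest

from fapsense import (
    GrowthParams,
    TransferModelParams,
    default_design,
    generate_plate,
    logistic_growth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def grid_12min():
    """240 samples at the 12-min reading interval (a 48 h run)."""
    return np.arange(240) * 12.0


@pytest.fixture(scope="session")
def logistic_input(grid_12min):
    """Benchmark biomass input: lag-free logistic from OD 0.05 to 1.2."""
    g = GrowthParams(x0=0.05, xmax=1.2, mu=0.01, lag=0.0)
    return logistic_growth(g, grid_12min)


@pytest.fixture(scope="session")
def model2():
    return TransferModelParams(k=250.84, tau_z=5.0, tau_p=(290.11, 12.69))


@pytest.fixture(scope="session")
def small_plate():
    """Two constructs x 6 doses x 2 replicates, 120 points; noisy."""
    design = default_design(
        constructs=("matCmatB", "matCatoDA"), replicates=2, n_times=120
    )
    return generate_plate(design, seed=7)
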