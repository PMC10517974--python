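import numpy as np
import pytest

from tissuestage import SolverGrid, SpeciesParams, TissueParams


@pytest.fixture
def tissue():
    """Carcinogenic-anchor tissue configuration (printed literature values)."""
    return TissueParams(phi=0.0022, Y=45.5e3)


@pytest.fixture
def species():
    return SpeciesParams()


@pytest.fixture
def coarse_grid():
    """Small solver grid for fast unit tests."""
    return SolverGrid(nx=48, steps_per_period=32, n_periods_max=6, tol_sigma=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
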