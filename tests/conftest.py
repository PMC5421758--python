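import numpy as np
import pytest

from gptimediff import (OptimizerSettings, SimConfig, TimeCourseSet,
                        simulate_dataset)


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-gene benchmark-style dataset shared across tests."""
    return simulate_dataset(SimConfig(n_genes=30, seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def shared_grid_tcs(rng):
    """Two replicates on a shared 3-point grid with fixed values."""
    times = np.array([0.0, 5.0, 10.0])
    return TimeCourseSet(
        gene_id="fixture",
        replicates=[(times, np.array([0.3, -0.5, 1.1])),
                    (times, np.array([-0.2, 0.4, 0.9]))],
    )


@pytest.fixture
def ragged_tcs():
    """Four replicates over ragged grids mimicking the treatment design."""
    r = np.random.default_rng(7)
    return TimeCourseSet(
        gene_id="ragged",
        replicates=[
            (np.array([0.0, 2.0, 6.0, 12.0, 24.0]), r.normal(size=5)),
            (np.array([0.0, 2.0, 6.0, 12.0, 24.0]), r.normal(size=5)),
            (np.array([2.0, 6.0, 12.0]), r.normal(size=3)),
            (np.array([6.0, 12.0, 24.0]), r.normal(size=3)),
        ],
    )


@pytest.fixture(scope="session")
def fast_optimizer():
    return OptimizerSettings(n_restarts=3, seed=0)
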