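import numpy as np
import pytest

from tumorfuse import Grid1D, sample_cohort, run_cohort


@pytest.fixture(scope="session")
def ref_grid():
    """Reference 1 mm-spacing grid used by hand-computed front examples."""
    return Grid1D(300.0, 301)


@pytest.fixture(scope="session")
def mini_cohort():
    """A small but fully simulated cohort shared across tests."""
    grid = Grid1D(400.0, 201)
    patients = sample_cohort(8, seed=42)
    run = run_cohort(patients, grid, horizon=36.0)
    return run


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
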