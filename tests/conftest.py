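import numpy as np
import pytest

from ovosex import make_default_grid, ratio_dataset
from ovosex.synthetic_data import CohortSimConfig, simulate_cohort


@pytest.fixture(scope="session")
def grid():
    return make_default_grid()


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded 8+8 cohort over all 13 days at the calibrated defaults."""
    sweeps, labels = simulate_cohort(CohortSimConfig(seed=1))
    return sweeps, labels


@pytest.fixture(scope="session")
def default_ratios(default_cohort):
    sweeps, labels = default_cohort
    ratios, _ = ratio_dataset(sweeps)
    return ratios, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20231)
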