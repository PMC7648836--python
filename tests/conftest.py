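import numpy as np
import pytest

from ctstrat.config import SimulationConfig
from ctstrat.simulate import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small full cohort shared by read-only tests."""
    config = SimulationConfig(n_reference=60, n_clinical=80, n_features=12,
                              n_parcels=4, n_sites=3, k_true=3,
                              deviation_amplitude=1.5, seed=11)
    covariates, features, clinical, truth = generate_cohort(config)
    return config, covariates, features, clinical, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
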