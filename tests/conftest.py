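import numpy as np
import pytest

from clonewell import ExperimentConfig, ModelParams, generate_growth_experiment


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def small_experiment():
    """One 20-well-per-group default-parameter ensemble, shared across
    tests that only read it."""
    return generate_growth_experiment(ExperimentConfig(wells_per_group=20, seed=2024))


@pytest.fixture()
def rng():
    return np.random.default_rng(17)
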