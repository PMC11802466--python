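import numpy as np
import pytest

from histoswarm.synthetic import SimulationConfig, generate_dataset

#: Single master seed for the expensive shared studies.
STUDY_SEED = 1


@pytest.fixture(scope="session")
def small_dataset():
    """A cheap 400-gene planted-motif sample for unit-level checks."""
    return generate_dataset(SimulationConfig(n_genes=400, seed=7))


@pytest.fixture(scope="session")
def recovery_study():
    """The full extract -> eliminate -> tune -> train study (fitted once)."""
    from histoswarm.experiments import run_recovery_study

    return run_recovery_study(STUDY_SEED)


@pytest.fixture(scope="session")
def null_study():
    """Label-permutation control study (fitted once)."""
    from histoswarm.experiments import run_null_study

    return run_null_study(STUDY_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
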