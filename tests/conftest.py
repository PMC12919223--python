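import numpy as np
import pytest

from adrdscreen.cohort import build_cohort
from adrdscreen.simulate import SimConfig, default_case_definition, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with ground truth, shared across tests."""
    config = SimConfig(n_case=60, n_control=600, seed=11)
    patients, truth = generate_cohort(config)
    return config, patients, truth


@pytest.fixture(scope="session")
def labeled_small_cohort(small_cohort):
    config, patients, truth = small_cohort
    labeled, tally = build_cohort(patients, default_case_definition(), config.cohort_config())
    return config, labeled, tally, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
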