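import numpy as np
import pytest

from runload.cohort import (CohortConfig, sample_cohort, sample_trials,
                            synthesize_kinematics)
from runload.pipeline import RunConfig, simulate_dataset


@pytest.fixture(scope="session")
def cohort_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def runner(cohort_config):
    return sample_cohort(1, seed=3, config=cohort_config)[0]


@pytest.fixture(scope="session")
def trial(runner, cohort_config):
    return sample_trials([runner], 1, (12.0, 12.0), seed=5,
                         config=cohort_config)[0]


@pytest.fixture(scope="session")
def kinematics(runner, trial, cohort_config):
    return synthesize_kinematics(runner, trial, seed=7, config=cohort_config)


@pytest.fixture(scope="session")
def tiny_data():
    """8 runners / 20 trials, all seven configurations."""
    return simulate_dataset(RunConfig(master_seed=11, n_runners=8,
                                      n_trials=20, n_splits=10))


@pytest.fixture(scope="session")
def study_data():
    """Replication-shaped synthetic study: 78 runners, 285 trials."""
    return simulate_dataset(RunConfig(master_seed=20, n_runners=78,
                                      n_trials=285))
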