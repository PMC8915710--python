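import numpy as np
import pytest

from ppgvol.feature_table import build_candidate_pool, features_from_cohort
from ppgvol.synthetic_cohort import (
    SimConfig,
    TrialLayout,
    simulate_cohort,
    synthesize_trial,
)


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def noiseless_config() -> SimConfig:
    return SimConfig().noiseless()


@pytest.fixture(scope="session")
def short_config() -> SimConfig:
    """Compact trials for IO and unit tests (keeps fixtures small)."""
    return SimConfig(
        trial_layout=TrialLayout(rest_s=10.0, strain_s=10.0, recovery_s=5.0),
        sampling_rate=50.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noiseless_trial(noiseless_config):
    """One zero-noise low-pressure trial with generator ground truth."""
    rng = np.random.default_rng(123)
    rec, ann, truth = synthesize_trial(
        5.0, noiseless_config, rng, heart_rate=60.0, return_truth=True
    )
    return rec, ann, truth


@pytest.fixture(scope="session")
def recovery_pool():
    """Default-condition cohort of 300 subjects, features and pool built.

    Session-scoped because simulation plus beat-level extraction is the
    expensive step shared by the parameter-recovery checks.
    """
    config = SimConfig(seed=42)
    subjects = simulate_cohort(300, config)
    table = features_from_cohort(subjects)
    return build_candidate_pool(table)
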