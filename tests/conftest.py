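import numpy as np
import pytest

from onsetscan import SimulationConfig, adjust_onset, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort (n = 1085, seed 1)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_adjusted(default_cohort):
    return adjust_onset(default_cohort)


@pytest.fixture(scope="session")
def smoke_cohort():
    """Tiny 20-subject cohort for plumbing tests."""
    return simulate_cohort(SimulationConfig(n_subjects=20, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20140726)
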