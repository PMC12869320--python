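import warnings

import numpy as np
import pytest

from tmrdecode import CohortConfig, generate_participant

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """Reduced-size study conditions for unit tests (fast to generate)."""
    return CohortConfig(n_sleep_trials=16, n_wake_trials_per_class=6)


@pytest.fixture(scope="session")
def participant(small_config):
    """One deterministic synthetic participant at the default conditions."""
    return generate_participant(small_config, participant_id=0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
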