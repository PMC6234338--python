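import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")

from cogbattery.cohort_sim import SimConfig, simulate_dataset  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(20150115)


@pytest.fixture(scope="session")
def small_dataset():
    """A shared moderate cohort over the three fast games."""
    cfg = SimConfig(seed=42, n_participants=150,
                    games=("spin", "react", "supersnap"))
    return cfg, simulate_dataset(cfg)
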