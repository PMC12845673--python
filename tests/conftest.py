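import numpy as np
import pytest

from bracekin import SimulationConfig, make_dataset


@pytest.fixture(scope="session")
def noise_free_mini():
    """3 participants x 2 tasks x 3 trials with every noise source zeroed."""
    cfg = SimulationConfig(
        n_participants=3, n_trials_per_task=3, seed=11,
        between_subject_peak_sd_deg=8.0, within_subject_peak_sd_deg=2.0,
    ).noise_free()
    return cfg, make_dataset(cfg, tasks=("walk", "sit"))


@pytest.fixture(scope="session")
def noisy_mini():
    """4 participants x 2 tasks x 3 trials at the default noise settings."""
    cfg = SimulationConfig(n_participants=4, n_trials_per_task=3, seed=7)
    return cfg, make_dataset(cfg, tasks=("walk", "stair"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
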