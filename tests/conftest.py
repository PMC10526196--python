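import numpy as np
import pytest

from fbadr.config import GeneratorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Smallest generator config that still exercises every stage."""
    return GeneratorConfig(
        n_subjects=1, n_trials=2, trial_s=15.0, fs=128.0, n_channels=6, seed=7
    )


def random_spd(rng, k: int, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    a = rng.standard_normal((k, k))
    return scale * (a @ a.T / k + np.eye(k))
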