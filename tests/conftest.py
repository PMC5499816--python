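import numpy as np
import pytest

from catackit.motif import MotifMatrix


def sharp_matrix(width: int, seed: int, dominant_prob: float = 0.9) -> MotifMatrix:
    """A well-determined random motif: one dominant base per position."""
    rng = np.random.default_rng(seed)
    probs = np.full((width, 4), (1 - dominant_prob) / 3)
    probs[np.arange(width), rng.integers(0, 4, size=width)] = dominant_prob
    return MotifMatrix(probs=probs)


@pytest.fixture(scope="session")
def catac_like_matrix() -> MotifMatrix:
    """A sharp 29-position matrix standing in for the CATAC PWM."""
    return sharp_matrix(29, seed=2024)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
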