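import numpy as np
import pytest


@pytest.fixture
def unit_square():
    return np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])


@pytest.fixture
def hexagon():
    ang = np.arange(6) * np.pi / 3
    return np.c_[np.cos(ang), np.sin(ang)]


@pytest.fixture
def disk_cloud():
    """Factory for uniform-disk clouds: disk_cloud(n, radius, seed)."""

    def make(n: int, radius: float = 60.0, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        r = radius * np.sqrt(rng.random(n))
        th = rng.random(n) * 2 * np.pi
        return np.c_[r * np.cos(th), r * np.sin(th)]

    return make
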