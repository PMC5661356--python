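import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from tacs.io import VideoStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_video(rng):
    """Small random video for oracle comparisons."""
    return VideoStack(rng.uniform(10.0, 50.0, size=(50, 6, 6)), frame_rate=10.0)


@pytest.fixture
def ramp_video():
    """Every pixel's time course is a*t + b with a > 0 (perfect correlation)."""
    t = np.arange(20, dtype=float)
    rng = np.random.default_rng(0)
    a = rng.uniform(0.5, 2.0, size=(5, 7))
    b = rng.uniform(0.0, 10.0, size=(5, 7))
    data = a[None] * t[:, None, None] + b[None]
    return VideoStack(data)
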