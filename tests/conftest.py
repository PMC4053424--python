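import numpy as np
import pytest

from pbodytrack.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small, fast simulation config at the 60-s acquisition mode."""
    return SimConfig(n_frames=60, dt=60.0, image_shape=(128, 128), rng_seed=1)


@pytest.fixture
def free_config():
    """Free diffusion only: hover pushed far outside the track."""
    return SimConfig(
        n_frames=60, dt=60.0, image_shape=(128, 128),
        hover_start_offset=-1e12, rng_seed=1,
    )
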