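import numpy as np
import pytest

from kymoclear.simulate import MotorGroundTruth, SimConfig, default_roi, render_kymograph


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Short movie, standard geometry (24 knt over 13 um, 15 s frames)."""
    return SimConfig(n_frames=30, seed=7)


@pytest.fixture(scope="session")
def single_motor(small_config):
    """One median-like motor: 63 nt/s, 3.9 knt, starting at frame 3."""
    return MotorGroundTruth("m0", 15000.0, 63.0, 3.9, 3)


@pytest.fixture(scope="session")
def clean_stack(small_config, single_motor):
    """Noiseless single-motor rendering with its ground truth."""
    stack, gt = render_kymograph([single_motor], small_config, noise=False)
    return stack, gt


@pytest.fixture(scope="session")
def noisy_stack(small_config, single_motor):
    stack, gt = render_kymograph(
        [single_motor], small_config, noise=True, rng=np.random.default_rng(42)
    )
    return stack, gt


@pytest.fixture(scope="session")
def roi(small_config):
    return default_roi(small_config)
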