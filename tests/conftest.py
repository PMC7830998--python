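import numpy as np
import pytest

from eggms.preprocess import AcquisitionSpec
from eggms.synthetic import EpisodeSpec, SimConfig


@pytest.fixture
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture
def quiet_config() -> SimConfig:
    """Noise-free session, no episodes: a pure 3 cpm slow wave."""
    return SimConfig(seed=1, noise_sd_uv=0.0)


@pytest.fixture
def episode_config() -> SimConfig:
    """Low-noise session with one strong amplitude episode in part B."""
    ep = EpisodeSpec(start_s=1440.0, end_s=1740.0, amp_gain=2.5,
                     press_rate_per_min=3.0)
    return SimConfig(seed=7, episodes=(ep,), noise_sd_uv=5.0)
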