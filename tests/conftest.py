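import numpy as np
import pytest

from gazecal.geometry import EyePose, rotation_from_euler
from gazecal.screen import default_screen
from gazecal.simulate import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def screen():
    return default_screen()


@pytest.fixture(scope="session")
def facing_eye():
    """Eye on the screen-centre normal at the chin-rest distance, facing it."""
    return EyePose(position=[0.0, 0.0, 140.0], rotation=rotation_from_euler(0, 0, 90))


@pytest.fixture(scope="session")
def noiseless_walking_session():
    """One noiseless walking session with both protocol phases (shared)."""
    cfg = SimulationConfig(seed=101, mobility="walking").noiseless()
    return cfg, simulate_session(cfg, protocol="both")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
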