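import numpy as np
import pytest

from ernano.io import PixelImage
from ernano.simulate import SimulationConfig, simulate_hole_field


@pytest.fixture()
def rng():
    return np.random.default_rng(20190107)


@pytest.fixture(scope="session")
def hole_field_100nm():
    """One simulated 25-hole field at 100-nm inner diameter, fixed seed."""
    config = SimulationConfig()
    image, truth = simulate_hole_field(config, rng=11)
    return config, image, truth


@pytest.fixture()
def constant_image():
    return PixelImage(np.full((32, 32), 7.0), 18.9)
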