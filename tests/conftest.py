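import numpy as np
import pytest

from besselao.bessel import AnnularMaskSpec
from besselao.config import OpticalConfig
from besselao.pupil import make_pupil_grid


@pytest.fixture(scope="session")
def cfg():
    """Default optical model: 940 nm, water, 25x/1.05 NA, 256-px pupil grid."""
    return OpticalConfig()


@pytest.fixture(scope="session")
def cfg_fine():
    """Finer grid for sampling-sensitive checks."""
    return OpticalConfig(grid_n=512)


@pytest.fixture(scope="session")
def disk(cfg):
    return make_pupil_grid(cfg)


@pytest.fixture(scope="session")
def hardware_mask(cfg):
    """Annulus derived from the printed 1.015/1.2-mm mask and relay chain."""
    return AnnularMaskSpec.from_hardware(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
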