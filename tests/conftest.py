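import numpy as np
import pytest

from ramanion.calibration import Calibration
from ramanion.synthetic import (DEFAULT_R0, DEFAULT_SOLUTES,
                                WaterSpectrumConfig, make_water_spectrum)


@pytest.fixture(scope="session")
def noiseless_config() -> WaterSpectrumConfig:
    return WaterSpectrumConfig(noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_water(noiseless_config):
    """A clean five-band solution spectrum with r = 1.363."""
    return make_water_spectrum(1.363, noiseless_config, seed=1)


@pytest.fixture(scope="session")
def nacl_calibration() -> Calibration:
    """The generating NaCl line, as an exact calibration object."""
    return Calibration(
        solute="NaCl",
        slope=DEFAULT_SOLUTES["NaCl"].slope,
        intercept=DEFAULT_R0,
        slope_se=0.0,
        intercept_se=0.0,
        r_squared=1.0,
        n_points=80,
        n_concentrations=4,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
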