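import numpy as np
import pytest

from cardiodwi.phantoms import PVP_ADC_M012, make_cardiac_phantom, make_pvp_phantom
from cardiodwi.waveforms import (EncodingSpec, HardwareLimits,
                                 design_motion_compensated,
                                 design_stejskal_tanner)


@pytest.fixture(scope="session")
def hw():
    return HardwareLimits()  # 440 mT/m, 3440 T/m/s, 10 us raster


@pytest.fixture(scope="session")
def st_wf(hw):
    """Stejskal-Tanner (M0) design at b = 350 s/mm^2."""
    return design_stejskal_tanner(EncodingSpec(350.0, 0), hw)


@pytest.fixture(scope="session")
def m012_wf(hw):
    """Second-order motion-compensated design at b = 350 s/mm^2."""
    return design_motion_compensated(EncodingSpec(350.0, 2), hw)


@pytest.fixture(scope="session")
def pvp_phantom():
    return make_pvp_phantom(PVP_ADC_M012)


@pytest.fixture(scope="session")
def cardiac_phantom():
    return make_cardiac_phantom()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
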