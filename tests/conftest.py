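import numpy as np
import pytest

from excispec import synthetic as syn
from excispec.tcspc import DecayCurve


@pytest.fixture(scope="session")
def grid_1024():
    """25 ns over 1024 channels (~24.4 ps bins): fast but resolves ~50 ps."""
    return syn.make_time_grid(1024, 25.0)


@pytest.fixture(scope="session")
def irf_1024(grid_1024):
    return syn.make_irf(syn.IRFSpec(fwhm=0.080, t0=2.0), grid_1024)


@pytest.fixture(scope="session")
def grid_256():
    return syn.make_time_grid(256, 25.0)


@pytest.fixture(scope="session")
def irf_256(grid_256):
    return syn.make_irf(syn.IRFSpec(fwhm=0.3, t0=2.0), grid_256)


@pytest.fixture()
def delta_irf_256(grid_256):
    """IRF that is numerically a single-channel spike at channel 0."""
    counts = np.zeros(grid_256.size)
    counts[0] = 1.0
    return DecayCurve(grid_256, counts)


@pytest.fixture(scope="session")
def duplex_components():
    return syn.PRESETS["duplex"][0]
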