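import numpy as np
import pytest

from twopeff import (
    PulseShapeSpec,
    SyntheticLaserSpec,
    SyntheticSceneSpec,
    generate_pulse,
)

FS = 1e-15
NJ = 1e-9


@pytest.fixture(scope="session")
def sech2_100fs():
    """Reference 100 fs sech² pulse, 12.5 nJ (1 W at 80 MHz)."""
    return generate_pulse(PulseShapeSpec("sech2", fwhm=100 * FS, energy=12.5 * NJ))


@pytest.fixture(scope="session")
def sech2_125fs():
    return generate_pulse(PulseShapeSpec("sech2", fwhm=125 * FS, energy=12.5 * NJ))


@pytest.fixture
def small_scene():
    """Compact scene for fast image-pipeline tests."""
    return SyntheticSceneSpec(image_shape=(128, 128), fwhm_lateral_px=6.0, fwhm_axial_px=18.0)


@pytest.fixture
def quiet_laser():
    return SyntheticLaserSpec("quiet", rep_rate=80e6, pulse_fwhm=100 * FS, noise_cv=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20230920)
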