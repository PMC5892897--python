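import numpy as np
import pytest

from pshgcal.calfit import fit_calibration
from pshgcal.polmodel import SystemParameters
from pshgcal.synth import VirtualMicroscope, acquire_calibration


@pytest.fixture(scope="session")
def bench_params() -> SystemParameters:
    """A realistic non-ideal instrument: moderate phase shift and attenuation,
    with motor offsets of the magnitude real mounts exhibit."""
    return SystemParameters(delta=25.0, gamma=0.9, phi0=71.0, theta0=32.0,
                            alpha0=15.0, I0=1.0)


@pytest.fixture(scope="session")
def noiseless_fit(bench_params):
    """Calibration fit of a noiseless coarse-protocol grid (shared: it is exact)."""
    vm = VirtualMicroscope(true_params=bench_params)
    return fit_calibration(acquire_calibration(vm))


@pytest.fixture(scope="session")
def noisy_fit(bench_params):
    """Calibration fit at 1% additive noise, for covariance-based tests."""
    vm = VirtualMicroscope(true_params=bench_params, noise_sigma=0.01, seed=42)
    return fit_calibration(acquire_calibration(vm), init=bench_params)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
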