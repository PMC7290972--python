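import math

import numpy as np
import pytest

from fgrscreen import SimulationConfig, simulate_cohort
from fgrscreen.spectrum import Spectrum


def make_gaussian_spectrum(
    peaks: dict[float, float],
    sigma: float = 4.0,
    baseline: float = 0.0,
    mz_range: tuple[float, float] = (4000.0, 20000.0),
    step: float = 1.0,
) -> Spectrum:
    """Analytic spectrum: Gaussian peaks of given {center: area} on a
    constant baseline — the closed-form oracle for integration tests."""
    mz = np.arange(mz_range[0], mz_range[1] + step, step)
    intensity = np.full_like(mz, float(baseline))
    for center, area in peaks.items():
        intensity += area / (sigma * math.sqrt(2 * math.pi)) * np.exp(
            -0.5 * ((mz - center) / sigma) ** 2
        )
    return Spectrum(mz, intensity)


@pytest.fixture(scope="session")
def gaussian_spectrum_factory():
    return make_gaussian_spectrum


@pytest.fixture(scope="session")
def small_cohort():
    """A small clean cohort shared by read-only tests."""
    config = SimulationConfig(n_ctrl=4, n_sga=2, n_fgr=4, seed=42)
    spectra, records = simulate_cohort(config)
    return config, spectra, records
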