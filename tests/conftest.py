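import numpy as np
import pytest

from photodose.spectra import PHOTON, SpectralIrradiance
from photodose.synthetic import ScenarioConfig, simulate_scenario


def flat_spectrum(value: float = 1.0, lo: float = 280.0, hi: float = 900.0,
                  step: float = 0.5, unit: str = PHOTON,
                  meta: dict | None = None) -> SpectralIrradiance:
    grid = np.arange(lo, hi + step / 2, step)
    return SpectralIrradiance(grid, np.full(grid.size, value), unit=unit,
                              meta=meta or {})


def smooth_random_spectrum(rng: np.random.Generator) -> SpectralIrradiance:
    """A positive smooth spectrum: a few broad Gaussian bumps on 280-900 nm."""
    grid = np.arange(280.0, 900.25, 0.5)
    values = np.full(grid.size, 0.1)
    for _ in range(rng.integers(2, 6)):
        centre = rng.uniform(280, 900)
        width = rng.uniform(30, 200)
        height = rng.uniform(0.1, 5.0)
        values = values + height * np.exp(-(((grid - centre) / width) ** 2))
    return SpectralIrradiance(grid, values, unit=PHOTON)


@pytest.fixture(scope="session")
def default_bundle():
    """One paper-shaped synthetic campaign, shared across tests."""
    return simulate_scenario(ScenarioConfig(), seed=11)
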