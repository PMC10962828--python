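import numpy as np
import pytest

from floravis.receptors import d65_illuminant, default_bee_receptors, equal_energy_illuminant
from floravis.spectra import ReflectanceSpectrum, WavelengthGrid
from floravis.synth import make_archetype


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.regular(300.0, 700.0, 1.0)


@pytest.fixture(scope="session")
def receptors(grid):
    return default_bee_receptors(grid)


@pytest.fixture(scope="session")
def d65(grid):
    return d65_illuminant(grid)


@pytest.fixture(scope="session")
def flat(grid):
    return equal_energy_illuminant(grid)


@pytest.fixture(scope="session")
def leaf(grid):
    return make_archetype("green_leaf", grid)


@pytest.fixture(scope="session")
def white_petal(grid):
    return make_archetype("white_petal", grid)


@pytest.fixture
def random_spectrum_factory(grid):
    """Smooth random reflectance spectra (mixtures of Gaussian bumps)."""

    def make(rng: np.random.Generator) -> ReflectanceSpectrum:
        wl = grid.values
        r = np.full(wl.size, rng.uniform(0.02, 0.2))
        for _ in range(rng.integers(1, 4)):
            center = rng.uniform(320, 680)
            sigma = rng.uniform(20, 80)
            amp = rng.uniform(0.05, 0.6)
            r = r + amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
        return ReflectanceSpectrum(grid=grid, reflectance=np.clip(r, 0.0, 1.0))

    return make
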