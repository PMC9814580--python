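import numpy as np
import pytest

from ramanmix import GridSpec, Spectrum
from ramanmix.synthetic_data import SEPARATED_PRESET, SimConfig, gen_subspectrum


@pytest.fixture
def fine_grid():
    return GridSpec(600.0, 1600.0, 0.5)


@pytest.fixture
def two_subspectra(fine_grid):
    """Two noise-free sub-spectra with three well-separated Lorentzian peaks each."""
    return [
        gen_subspectrum(
            SEPARATED_PRESET[i],
            SimConfig(seed=100 + i, noise_sigma=0.0, grid_spec=fine_grid),
            label=f"sub{i}",
        )
        for i in range(2)
    ]


@pytest.fixture
def three_subspectra(fine_grid):
    return [
        gen_subspectrum(
            SEPARATED_PRESET[i],
            SimConfig(seed=100 + i, noise_sigma=0.0, grid_spec=fine_grid),
            label=f"sub{i}",
        )
        for i in range(3)
    ]


@pytest.fixture
def simple_spectrum():
    grid = np.linspace(600.0, 1600.0, 501)
    y = np.exp(-0.5 * ((grid - 1000.0) / 30.0) ** 2)
    return Spectrum(grid, y, label="gauss")
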