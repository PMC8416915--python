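import numpy as np
import pytest

from anthoscan import (
    HyperspectralCube,
    LeafSimParams,
    PanelRegion,
    ReflectanceCube,
    simulate_leaf_cube,
    to_reflectance,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_reflectance(spectra, wavelengths):
    """Build a ReflectanceCube directly from per-pixel spectra.

    ``spectra`` is (lines, samples, bands); white_stats is all-ones since the
    values are already reflectance.
    """
    spectra = np.asarray(spectra, dtype=float)
    return ReflectanceCube(
        data=spectra,
        wavelengths=np.asarray(wavelengths, dtype=float),
        white_stats=np.ones(spectra.shape[2]),
    )


def single_pixel_refl(spectrum, wavelengths):
    return make_reflectance(np.asarray(spectrum)[None, None, :], wavelengths)


@pytest.fixture
def tiny_cube():
    """2 x 2 x 3 cube with hand-enumerable values 0..11 (cube[l,s,b] = 6l+3s+b)."""
    data = np.arange(12, dtype=np.float64).reshape(2, 2, 3)
    return HyperspectralCube(
        data=data, wavelengths=np.array([500.0, 600.0, 700.0]), meta={"sensor": "toy"}
    )


@pytest.fixture
def noise_free_leaf():
    """A default noise-free simulated leaf plus its reflectance cube."""
    sim = simulate_leaf_cube(LeafSimParams(anthocyanin=6.0, noise_sd=0.0, seed=7))
    refl = to_reflectance(sim.cube, sim.panel)
    return sim, refl
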