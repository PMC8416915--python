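"""Synthetic data generators: every input the pipeline needs, with known truth.

The leaf forward model is a reciprocal-linear (Kubelka–Munk-type) absorption
model: for a scattering leaf, reciprocal reflectance is approximately linear
in the absorption coefficient, which is exactly the premise of 1/R-type
anthocyanin indices.  Tissue reflectance is

    R(λ) = R_base / (1 + k_a·TA·g_a(λ) + k_c·Chl·g_c(λ))

with a spectrally flat base reflectance R_base = 0.55 (pigment-free tissue is
uniformly bright out to the NIR plateau), a Gaussian anthocyanin absorption
profile g_a centered at 550 nm (σ = 40 nm) and a chlorophyll profile g_c at
670 nm (σ = 30 nm) — the red edge emerges from the chlorophyll term itself.
k_a = 0.1 per (mg/g) is set so that 10 mg/g of anthocyanin halves R at
550 nm; k_c = 0.19 per unit chlorophyll puts the default leaf (Chl = 25) at
NDVI ≈ 0.70 against the flat white panel.  Under this model the modified
anthocyanin reflectance index is exactly linear in TA at zero noise, and a
pigment-free leaf has index 0.

The sensor grid emulates a 128-band visible/NIR line-scan imager with
4.69 nm spectral resolution starting at 400 nm; test cubes default to
64 × 64 pixels (full 520 × 696 frames are available via ``shape``).

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import AbsorbanceSpectrum, AssayParams
from .hsi_io import HyperspectralCube, PanelRegion
from .segmentation import LeafMask

__all__ = [
    "LeafSimParams",
    "SimulatedLeaf",
    "GxeDesign",
    "default_sensor_wavelengths",
    "simulate_leaf_cube",
    "simulate_rgb_leaf",
    "simulate_gxe_table",
    "simulate_absorbance",
]

# Forward-model constants (see module docstring for the calibration rationale).
PANEL_REFLECTANCE = 0.95
BASE_REFLECTANCE = 0.55
K_ANTHOCYANIN_PER_MG_G = 0.1    # 10 mg/g halves R(550)
K_CHLOROPHYLL_PER_UNIT = 0.19   # Chl = 25 gives leaf NDVI ~ 0.70
ANTHOCYANIN_CENTER_NM = 550.0
ANTHOCYANIN_SIGMA_NM = 40.0
CHLOROPHYLL_CENTER_NM = 670.0
CHLOROPHYLL_SIGMA_NM = 30.0

SENSOR_BANDS = 128
SENSOR_RESOLUTION_NM = 4.69
SENSOR_START_NM = 400.0
FULL_FRAME_SHAPE = (520, 696)


def default_sensor_wavelengths() -> np.ndarray:
    """Band centers of the emulated 128-band, 4.69 nm visible/NIR imager."""
    return SENSOR_START_NM + SENSOR_RESOLUTION_NM * np.arange(SENSOR_BANDS)


@dataclass(frozen=True)
class LeafSimParams:
    """Parameters of one simulated leaf-on-panel hyperspectral acquisition.

    ``anthocyanin`` is in mg/g DW; ``chlorophyll`` in arbitrary units (the
    default 25 gives a realistic red-edge contrast); ``noise_sd`` is additive
    Gaussian noise in reflectance units; ``gain`` converts model reflectance
    to sensor counts (indices are invariant to it by construction).
    """

    anthocyanin: float = 5.0
    chlorophyll: float = 25.0
    leaf_axes: tuple[float, float] = (18.0, 12.0)
    noise_sd: float = 0.0
    seed: int = 0
    shape: tuple[int, int] = (64, 64)
    gain: float = 1000.0
    wavelengths: np.ndarray = field(default_factory=default_sensor_wavelengths)

    def __post_init__(self) -> None:
        if self.anthocyanin < 0:
            raise ValueError("anthocyanin must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if min(self.shape) < 8:
            raise ValueError("image must be at least 8 pixels on each side")


@dataclass
class SimulatedLeaf:
    """A simulated cube together with its generating ground truth."""

    cube: HyperspectralCube
    truth_mask: LeafMask
    anthocyanin: float
    panel: PanelRegion


def leaf_reflectance_spectrum(
    wavelengths: np.ndarray, anthocyanin: float, chlorophyll: float
) -> np.ndarray:
    """Noise-free tissue reflectance under the reciprocal-linear pigment model."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    g_a = np.exp(-((wavelengths - ANTHOCYANIN_CENTER_NM) ** 2)
                 / (2 * ANTHOCYANIN_SIGMA_NM**2))
    g_c = np.exp(-((wavelengths - CHLOROPHYLL_CENTER_NM) ** 2)
                 / (2 * CHLOROPHYLL_SIGMA_NM**2))
    absorption = (K_ANTHOCYANIN_PER_MG_G * anthocyanin * g_a
                  + K_CHLOROPHYLL_PER_UNIT * chlorophyll * g_c)
    return BASE_REFLECTANCE / (1.0 + absorption)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float]) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (((rows - center[0]) / axes[0]) ** 2
            + ((cols - center[1]) / axes[1]) ** 2) <= 1.0


def simulate_leaf_cube(params: LeafSimParams) -> SimulatedLeaf:
    """Simulate an elliptical leaf on a white reference panel.

    Panel pixels sit at flat reflectance 0.95; leaf pixels follow the pigment
    model at the requested anthocyanin/chlorophyll load.  Gaussian noise of
    sd ``noise_sd`` (reflectance units) is added everywhere, the result
    clipped at 0 and scaled by ``gain`` into raw counts.  The returned panel
    region is a top strip guaranteed clear of the leaf.
    """
    lines, samples = params.shape
    center = (0.58 * lines, 0.5 * samples)
    mask = _ellipse_mask(params.shape, center, params.leaf_axes)

    leaf_spec = leaf_reflectance_spectrum(
        params.wavelengths, params.anthocyanin, params.chlorophyll
    )
    refl = np.empty((lines, samples, len(params.wavelengths)))
    refl[:] = PANEL_REFLECTANCE
    refl[mask] = leaf_spec

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        refl = refl + rng.normal(0.0, params.noise_sd, size=refl.shape)
    counts = np.clip(refl, 0.0, None) * params.gain

    panel_rows = max(4, lines // 10)
    panel = PanelRegion(0, panel_rows, 0, samples)
    cube = HyperspectralCube(
        data=counts,
        wavelengths=np.asarray(params.wavelengths, dtype=float),
        meta={"description": "synthetic leaf on white reference panel",
              "anthocyanin_mg_per_g": f"{params.anthocyanin}"},
    )
    return SimulatedLeaf(cube=cube, truth_mask=LeafMask(mask),
                         anthocyanin=params.anthocyanin, panel=panel)


@dataclass
class SimulatedRgbLeaf:
    image: np.ndarray
    truth_mask: LeafMask
    purple_fraction: float


def simulate_rgb_leaf(
    purple_fraction: float,
    ref_color: tuple[float, float, float] = (0.45, 0.20, 0.45),
    seed: int = 0,
    shape: tuple[int, int] = (128, 128),
    jitter: float = 0.02,
    green: tuple[float, float, float] = (0.20, 0.50, 0.20),
) -> SimulatedRgbLeaf:
    """An elliptical leaf on white with a controlled purple-pixel fraction.

    Exactly ``round(purple_fraction × leaf_pixels)`` randomly chosen leaf
    pixels take ``ref_color`` (± per-channel Gaussian jitter of sd
    ``jitter``), the rest ``green``.  The returned ``purple_fraction`` is the
    exact realized fraction.
    """
    if not (0.0 <= purple_fraction <= 1.0):
        raise ValueError("purple_fraction must lie in [0, 1]")
    rows, cols = shape
    mask = _ellipse_mask(shape, (rows / 2, cols / 2), (0.38 * rows, 0.30 * cols))
    image = np.ones((rows, cols, 3))
    image[mask] = green

    rng = np.random.default_rng(seed)
    leaf_idx = np.flatnonzero(mask)
    n_purple = round(purple_fraction * leaf_idx.size)
    chosen = rng.choice(leaf_idx, size=n_purple, replace=False)
    flat = image.reshape(-1, 3)
    flat[chosen] = ref_color
    if jitter > 0:
        flat[leaf_idx] = np.clip(
            flat[leaf_idx] + rng.normal(0.0, jitter, size=(leaf_idx.size, 3)),
            0.0, 1.0,
        )
    return SimulatedRgbLeaf(
        image=image,
        truth_mask=LeafMask(mask),
        purple_fraction=n_purple / leaf_idx.size,
    )


@dataclass(frozen=True)
class GxeDesign:
    """A balanced genotype × treatment design with additive known effects.

    Cell expectation = genotype_mean + environment_effect + interaction;
    replicate noise is iid Gaussian with sd ``replicate_sd``.  The defaults
    mirror the trial structure this package targets: 4 cultivars × 4
    treatments × 4 replicates.
    """

    genotype_means: dict = field(
        default_factory=lambda: {"G1": 0.8, "G2": 8.0, "G3": 3.3, "G4": 0.9}
    )
    environment_effects: dict = field(
        default_factory=lambda: {"NC-GS1": -0.6, "SC-GS1": 0.7,
                                 "NC-GS2": -0.5, "SC-GS2": 0.4}
    )
    interaction_effects: dict = field(default_factory=dict)
    replicate_sd: float = 0.1
    n_reps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if self.replicate_sd < 0:
            raise ValueError("replicate_sd must be non-negative")


def simulate_gxe_table(design: GxeDesign) -> pd.DataFrame:
    """Replicate-level sample table drawn from an additive G×E design."""
    rng = np.random.default_rng(design.seed)
    records = []
    for g, g_mean in design.genotype_means.items():
        for e, e_eff in design.environment_effects.items():
            cell = g_mean + e_eff + design.interaction_effects.get((g, e), 0.0)
            noise = (rng.normal(0.0, design.replicate_sd, size=design.n_reps)
                     if design.replicate_sd > 0 else np.zeros(design.n_reps))
            for rep in range(design.n_reps):
                records.append(
                    {"genotype": g, "treatment": e, "replicate": rep + 1,
                     "value": cell + noise[rep]}
                )
    return pd.DataFrame.from_records(records)


def simulate_absorbance(
    anthocyanin_mg_per_g: float,
    assay: AssayParams | None = None,
    dilution_factor: float = 1.0,
    extract_volume_ml: float = 12.5,
    dry_mass_g: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AbsorbanceSpectrum:
    """Extract absorbance spectrum whose assay readout equals the given TA.

    The peak is a Gaussian at the assay's peak wavelength, shifted and
    clamped so the spectrum is exactly zero at (and beyond) the baseline
    wavelength — the baseline-corrected peak absorbance then equals the
    target exactly at zero noise, making the generator the exact inverse of
    the quantification formula.
    """
    if anthocyanin_mg_per_g < 0:
        raise ValueError("anthocyanin must be non-negative")
    assay = assay or AssayParams()
    wavelengths = np.arange(400.0, 801.0, 2.0)

    target_a = (
        (anthocyanin_mg_per_g / 1000.0)
        * assay.extinction_l_per_mol_cm * assay.path_cm * dry_mass_g
    ) / (assay.molar_mass_g_per_mol * dilution_factor * (extract_volume_ml / 1000.0))

    sigma = 40.0
    profile = np.exp(-((wavelengths - assay.peak_nm) ** 2) / (2 * sigma**2))
    at_baseline = np.exp(-((assay.baseline_nm - assay.peak_nm) ** 2) / (2 * sigma**2))
    shape = np.clip(profile - at_baseline, 0.0, None) / (1.0 - at_baseline)
    absorbance = target_a * shape
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = np.clip(
            absorbance + rng.normal(0.0, noise_sd, size=absorbance.shape), 0.0, None
        )
        # Keep the baseline reading itself noise-free in expectation terms:
        # noise is clipped at zero, not removed.
    return AbsorbanceSpectrum(
        wavelengths_nm=wavelengths,
        absorbance=absorbance,
        dilution_factor=dilution_factor,
        extract_volume_ml=extract_volume_ml,
        dry_mass_g=dry_mass_g,
    )
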