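"""Wet-chemistry anthocyanin quantification from extract absorbance spectra.

This is the "destructive" reference channel: leaf tissue is freeze-dried,
extracted in aqueous methanol, and the extract's absorbance read around the
anthocyanin peak.  Content is computed by a standard single-peak,
baseline-corrected extinction-coefficient quantification in
cyanidin-3-glucoside equivalents:

    mg/g DW = (A_peak − A_baseline) · MW · DF · V / (ε · l · m) · 1000

with MW the molar mass (g/mol), DF the dilution factor, V the extract volume
(L), ε the molar extinction coefficient (L·mol⁻¹·cm⁻¹), l the optical path
(cm) and m the dry mass (g).  Every constant is explicit configuration; the
module's role in this package is unit bookkeeping and synthetic ground-truth
generation, not wet-lab fidelity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .hsi_io import nearest_band

__all__ = ["AssayParams", "AbsorbanceSpectrum", "anthocyanin_mg_per_g"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssayParams:
    """Constants of the extinction-coefficient quantification.

    Defaults are cyanidin-3-glucoside equivalents: molar mass 449.2 g/mol,
    ε = 26,900 L·mol⁻¹·cm⁻¹, 1 cm path, peak 550 nm baselined at 700 nm.
    """

    molar_mass_g_per_mol: float = 449.2
    extinction_l_per_mol_cm: float = 26_900.0
    path_cm: float = 1.0
    peak_nm: float = 550.0
    baseline_nm: float = 700.0

    def __post_init__(self) -> None:
        if min(self.molar_mass_g_per_mol, self.extinction_l_per_mol_cm, self.path_cm) <= 0:
            raise ValueError("assay constants must be positive")


@dataclass
class AbsorbanceSpectrum:
    """An extract absorbance spectrum plus the extraction bookkeeping.

    ``extract_volume_ml`` defaults to 12.5 mL (0.5 g dry tissue in 10 mL of
    70% methanol, diluted with water to 1.25× the extract volume).
    """

    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    dilution_factor: float = 1.0
    extract_volume_ml: float = 12.5
    dry_mass_g: float = 0.5

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths_nm.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance vectors must have equal length")
        if self.dry_mass_g <= 0:
            raise ValueError("dry mass must be positive")
        if np.any(self.absorbance < 0):
            raise ValueError("absorbance must be non-negative")


def anthocyanin_mg_per_g(
    spectrum: AbsorbanceSpectrum, params: AssayParams | None = None
) -> float:
    """Anthocyanin content in mg per g dry weight from an absorbance spectrum.

    The peak and baseline wavelengths are read at the nearest sampled points
    (an error if either lies outside the spectrum's range).  A negative
    baseline-corrected absorbance is clamped to zero with a warning — it
    indicates a baseline artifact, not negative pigment.
    """
    params = params or AssayParams()
    a_peak = spectrum.absorbance[nearest_band(spectrum.wavelengths_nm, params.peak_nm)]
    a_base = spectrum.absorbance[
        nearest_band(spectrum.wavelengths_nm, params.baseline_nm)
    ]
    corrected = float(a_peak - a_base)
    if corrected < 0:
        logger.warning(
            "negative baseline-corrected absorbance (%.4g); clamping to 0", corrected
        )
        corrected = 0.0
    grams_per_gram = (
        corrected
        * params.molar_mass_g_per_mol
        * spectrum.dilution_factor
        * (spectrum.extract_volume_ml / 1000.0)
    ) / (params.extinction_l_per_mol_cm * params.path_cm * spectrum.dry_mass_g)
    return grams_per_gram * 1000.0
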