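"""Leaf/background segmentation for reflectance cubes and RGB photographs.

The imaging protocol places the leaf on a bright white reference panel, so
segmentation reduces to separating vegetation from a spectrally flat (or
near-white) background.  For hyperspectral input an NDVI threshold is used:
any leaf — green or purple — has a strong red-edge contrast (NDVI well above
0), while the flat panel sits at NDVI ≈ 0.  For RGB input the background is
near-white, so a pixel is background iff its darkest channel is brighter than
a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hsi_io import ReflectanceCube, SpectralWindow, band_window_mean, nearest_band

__all__ = ["LeafMask", "segment_leaf_hsi", "segment_leaf_rgb", "NIR_WINDOW"]

#: NIR plateau window shared with the anthocyanin indices.
NIR_WINDOW = SpectralWindow(759.5, 797.02)

#: Connected components smaller than this (pixels) are treated as specks and
#: removed; leaf-level index means are sensitive to stray background pixels.
DEFAULT_MIN_AREA = 50


@dataclass
class LeafMask:
    """Boolean leaf mask with the same spatial shape as its source image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("leaf mask must be 2-D")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _remove_small_components(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.isin(labels, 1 + np.nonzero(sizes >= min_area)[0])
    return keep


def segment_leaf_hsi(
    refl: ReflectanceCube,
    ndvi_threshold: float = 0.3,
    red_nm: float = 670.0,
    nir_window: SpectralWindow = NIR_WINDOW,
    min_area: int = DEFAULT_MIN_AREA,
) -> LeafMask:
    """Segment leaf pixels by NDVI = (R_nir − R_red) / (R_nir + R_red).

    R_red is the reflectance at the band nearest ``red_nm`` (chlorophyll
    absorption) and R_nir the mean over ``nir_window``.  Pixels whose
    denominator is 0 are background.  Raising the threshold can only shrink
    the mask.
    """
    if not (-1.0 < ndvi_threshold < 1.0):
        raise ValueError("ndvi_threshold must lie in (-1, 1)")
    red = refl.data[:, :, nearest_band(refl.wavelengths, red_nm)]
    nir = band_window_mean(refl, nir_window)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom > 0, (nir - red) / denom, -1.0)
    mask = ndvi > ndvi_threshold
    return LeafMask(_remove_small_components(mask, min_area))


def segment_leaf_rgb(
    image: np.ndarray,
    background_brightness: float = 0.85,
    min_area: int = DEFAULT_MIN_AREA,
) -> LeafMask:
    """Segment a leaf from a near-white background in an RGB photograph.

    ``image`` is an (H, W, 3) array with channels in [0, 1].  A pixel is
    background iff min(R, G, B) > ``background_brightness``; the leaf is the
    complement, with connected components below ``min_area`` removed.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("RGB image must have shape (H, W, 3)")
    if image.min() < 0 or image.max() > 1:
        raise ValueError("RGB channels must be normalized to [0, 1]")
    mask = image.min(axis=2) <= background_brightness
    return LeafMask(_remove_small_components(mask, min_area))
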