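"""Purple/red leaf-area scoring from RGB photographs.

A pixel "expresses" a reference color when each of its channels lies within a
tolerance band of that reference — by default a relative band of ±20% of each
reference channel value, all three channels required.  The score is the
percentage of leaf pixels matching, a cheap camera-only proxy for anthocyanin
accumulation: it tracks *where* pigment is expressed but saturates and cannot
resolve pigment concentration within already-colored tissue.

Reference colors are explicit configuration, never hidden constants; the
defaults below are generic leaf purple/red anchors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .segmentation import LeafMask

__all__ = [
    "ColorReference",
    "ColorAreaResult",
    "DEFAULT_REFERENCES",
    "read_rgb_image",
    "write_rgb_image",
    "color_correct",
    "color_area_pct",
]


@dataclass(frozen=True)
class ColorReference:
    """A named reference color with a per-channel tolerance fraction."""

    name: str
    rgb: tuple[float, float, float]
    tolerance: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance < 1.0):
            raise ValueError("tolerance must lie in (0, 1)")
        if any(not (0.0 < c <= 1.0) for c in self.rgb):
            raise ValueError("reference channels must lie in (0, 1]")


DEFAULT_REFERENCES: dict[str, ColorReference] = {
    "purple": ColorReference("purple", (0.45, 0.20, 0.45)),
    "red": ColorReference("red", (0.60, 0.15, 0.20)),
}


@dataclass(frozen=True)
class ColorAreaResult:
    """Count of leaf pixels matching a color reference, as a percentage."""

    matched_pixels: int
    leaf_pixels: int
    reference: ColorReference

    @property
    def percentage(self) -> float:
        return 100.0 * self.matched_pixels / self.leaf_pixels


def read_rgb_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def write_rgb_image(image: np.ndarray, path: str | Path) -> None:
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def color_correct(
    image: np.ndarray,
    card_patches: Iterable[tuple[Sequence[float], Sequence[float]]],
) -> np.ndarray:
    """Apply per-channel linear gains derived from color-card patch pairs.

    ``card_patches`` pairs (measured_rgb, reference_rgb) for neutral patches;
    the gain per channel is mean(reference) / mean(measured).  Output is
    clipped to [0, 1].  A full 3×3 color matrix is deliberately not fitted —
    neutral-patch gains are reproducible from a single patch and sufficient
    for threshold-based area scoring.
    """
    pairs = list(card_patches)
    if not pairs:
        raise ValueError("need at least one card patch pair")
    measured = np.array([p[0] for p in pairs], dtype=float)
    reference = np.array([p[1] for p in pairs], dtype=float)
    meas_mean = measured.mean(axis=0)
    if np.any(meas_mean <= 0):
        raise ValueError("measured patch channel mean is zero")
    gains = reference.mean(axis=0) / meas_mean
    return np.clip(np.asarray(image, dtype=float) * gains, 0.0, 1.0)


def _match_relative(image: np.ndarray, ref: ColorReference) -> np.ndarray:
    ref_rgb = np.asarray(ref.rgb)
    return np.all(np.abs(image - ref_rgb) <= ref.tolerance * ref_rgb, axis=2)


def _match_absolute(image: np.ndarray, ref: ColorReference) -> np.ndarray:
    ref_rgb = np.asarray(ref.rgb)
    return np.all(np.abs(image - ref_rgb) <= ref.tolerance, axis=2)


def _match_hsv(image: np.ndarray, ref: ColorReference) -> np.ndarray:
    # Relative band applied in HSV space; hue distance is taken on the circle.
    from matplotlib.colors import rgb_to_hsv

    hsv = rgb_to_hsv(image)
    ref_hsv = rgb_to_hsv(np.asarray(ref.rgb)[None, None, :])[0, 0]
    dh = np.abs(hsv[..., 0] - ref_hsv[0])
    dh = np.minimum(dh, 1.0 - dh)
    ok_h = dh <= ref.tolerance * max(ref_hsv[0], 1e-9)
    ok_s = np.abs(hsv[..., 1] - ref_hsv[1]) <= ref.tolerance * max(ref_hsv[1], 1e-9)
    ok_v = np.abs(hsv[..., 2] - ref_hsv[2]) <= ref.tolerance * max(ref_hsv[2], 1e-9)
    return ok_h & ok_s & ok_v


_MATCHERS = {
    "relative": _match_relative,
    "absolute": _match_absolute,
    "hsv": _match_hsv,
}


def color_area_pct(
    image: np.ndarray,
    mask: LeafMask,
    ref: ColorReference,
    mode: str = "relative",
) -> ColorAreaResult:
    """Percentage of leaf pixels within the tolerance band of ``ref``.

    ``mode`` selects the band definition: "relative" (±tolerance × reference
    channel value, the default), "absolute" (±tolerance in channel units), or
    "hsv" (relative band in HSV space).
    """
    image = np.asarray(image, dtype=float)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    if mask.pixel_count == 0:
        raise ValueError("no leaf pixels in mask")
    try:
        matcher = _MATCHERS[mode]
    except KeyError:
        raise ValueError(f"unknown match mode {mode!r}; one of {sorted(_MATCHERS)}") from None
    matched = matcher(image, ref) & mask.mask
    return ColorAreaResult(
        matched_pixels=int(matched.sum()),
        leaf_pixels=mask.pixel_count,
        reference=ref,
    )
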