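"""ENVI-style hyperspectral cube I/O and reflectance calibration.

A cube is held in memory as a ``lines × samples × bands`` array regardless of
the on-disk interleave.  Reflectance is computed against the per-band spatial
mean of a white reference panel placed in the scene: the panel both provides
the radiometric reference and monitors the (uncontrolled) indoor illumination,
so dividing by its per-band mean removes the illumination spectrum and any
global gain in a single step.

Coordinates are 0-based, row-major; regions are half-open.  Reflectance is
deliberately *not* clipped to [0, 1] — specular pixels above 1 are preserved
and left to downstream masking, because clipping would bias spectral window
means.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "HyperspectralCube",
    "ReflectanceCube",
    "PanelRegion",
    "SpectralWindow",
    "read_envi_cube",
    "write_envi_cube",
    "nearest_band",
    "to_reflectance",
    "band_window_mean",
]

# ENVI numeric codes for the data types this reader supports (little-endian).
_ENVI_DTYPES = {4: np.dtype("<f4"), 12: np.dtype("<u2")}
_DTYPE_CODES = {np.dtype("<f4"): 4, np.dtype("<u2"): 12}

# On-disk axis order of each interleave, expressed as the permutation that
# maps a (lines, samples, bands) array onto the file layout.
_INTERLEAVE_AXES = {
    "bsq": (2, 0, 1),  # band, line, sample
    "bil": (0, 2, 1),  # line, band, sample
    "bip": (0, 1, 2),  # line, sample, band
}


@dataclass
class HyperspectralCube:
    """Raw sensor counts on a lines × samples × bands grid.

    ``wavelengths`` holds band-center wavelengths in nm and must be strictly
    increasing with one entry per band.  ``meta`` carries free-form header
    fields (sensor name, acquisition notes) and is preserved on round trip.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (lines, samples, bands)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength list length {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.data < 0):
            raise ValueError("raw cube values must be non-negative")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class ReflectanceCube:
    """White-panel-normalized reflectance with the same geometry as the raw cube.

    ``white_stats`` records the per-band panel mean used for normalization so
    the calibration is auditable and invertible.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    white_stats: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.white_stats = np.asarray(self.white_stats, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if len(self.wavelengths) != self.data.shape[2]:
            raise ValueError("wavelength list does not match band dimension")

    @property
    def lines(self) -> int:
        return self.data.shape[0]

    @property
    def samples(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class PanelRegion:
    """Half-open, 0-based row/column bounds of the white reference panel."""

    row0: int
    row1: int
    col0: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValueError("panel region must be non-empty")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("panel region bounds must be non-negative")

    @classmethod
    def from_string(cls, spec: str) -> "PanelRegion":
        """Parse ``"row0:row1,col0:col1"`` as used on the command line."""
        m = re.fullmatch(r"\s*(\d+):(\d+)\s*,\s*(\d+):(\d+)\s*", spec)
        if m is None:
            raise ValueError(f"cannot parse panel region {spec!r}; expected r0:r1,c0:c1")
        return cls(*(int(g) for g in m.groups()))

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row0, self.row1), slice(self.col0, self.col1)


@dataclass(frozen=True)
class SpectralWindow:
    """Closed wavelength interval [lo_nm, hi_nm] selecting whole bands."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self) -> None:
        if self.lo_nm > self.hi_nm:
            raise ValueError("window lo_nm must not exceed hi_nm")

    def band_indices(self, wavelengths: np.ndarray) -> np.ndarray:
        wavelengths = np.asarray(wavelengths, dtype=float)
        idx = np.nonzero((wavelengths >= self.lo_nm) & (wavelengths <= self.hi_nm))[0]
        return idx


def _parse_envi_header(text: str) -> dict:
    """Parse ENVI ``key = value`` pairs; brace values may span lines."""
    header: dict = {}
    # Strip the leading "ENVI" magic line if present.
    body = re.sub(r"^\s*ENVI\s*\n", "", text, count=1)
    pattern = re.compile(r"^\s*([^=\n]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.M | re.S)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        value = m.group(2).strip()
        if value.startswith("{"):
            value = value[1:-1].strip()
        header[key] = value
    return header


def _data_path_for_header(header_path: Path) -> Path:
    """Locate the binary file paired with an ENVI header."""
    stem = header_path.with_suffix("")
    for candidate in (stem, stem.with_suffix(".img"), stem.with_suffix(".dat"),
                      stem.with_suffix(".raw")):
        if candidate.exists() and candidate != header_path:
            return candidate
    raise FileNotFoundError(f"no data file found next to header {header_path}")


def read_envi_cube(header_path: str | Path) -> HyperspectralCube:
    """Read an ENVI header + binary cube into a (lines, samples, bands) array.

    Supports BSQ/BIL/BIP interleaves, little-endian unsigned 16-bit (type 12)
    and 32-bit float (type 4) data.  The header must declare a wavelength
    list whose length equals the band count.
    """
    header_path = Path(header_path)
    header = _parse_envi_header(header_path.read_text())

    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in header:
            raise ValueError(f"ENVI header missing required field {key!r}")
    if "wavelength" not in header:
        raise ValueError("no wavelengths in ENVI header")

    lines = int(header["lines"])
    samples = int(header["samples"])
    bands = int(header["bands"])
    dtype_code = int(header["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    if int(header.get("byte order", 0)) != 0:
        raise ValueError("only little-endian (byte order = 0) cubes are supported")
    interleave = header["interleave"].strip().lower()
    if interleave not in _INTERLEAVE_AXES:
        raise ValueError(f"unsupported interleave {interleave!r}")

    wavelengths = np.array(
        [float(tok) for tok in re.split(r"[,\s]+", header["wavelength"]) if tok],
        dtype=float,
    )
    if len(wavelengths) != bands:
        raise ValueError(
            f"header declares {bands} bands but {len(wavelengths)} wavelengths"
        )

    raw = np.fromfile(_data_path_for_header(header_path), dtype=_ENVI_DTYPES[dtype_code])
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(f"data file holds {raw.size} values, expected {expected}")

    axes = _INTERLEAVE_AXES[interleave]
    disk_shape = tuple((lines, samples, bands)[a] for a in axes)
    cube = raw.reshape(disk_shape).transpose(np.argsort(axes))

    meta = {
        k: v
        for k, v in header.items()
        if k not in {"samples", "lines", "bands", "data type", "interleave",
                     "wavelength", "byte order", "header offset"}
    }
    return HyperspectralCube(data=cube, wavelengths=wavelengths, meta=meta)


def write_envi_cube(
    cube: HyperspectralCube,
    header_path: str | Path,
    interleave: str = "bsq",
    dtype: str | np.dtype = "float32",
) -> Path:
    """Write a cube as ENVI header + raw binary; returns the data-file path.

    The default output is BSQ float32; BIL/BIP and uint16 are available for
    interoperability testing.
    """
    header_path = Path(header_path)
    interleave = interleave.lower()
    if interleave not in _INTERLEAVE_AXES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dt = np.dtype(dtype).newbyteorder("<")
    if dt not in _DTYPE_CODES:
        raise ValueError(f"unsupported output dtype {dtype!r}")

    axes = _INTERLEAVE_AXES[interleave]
    disk = np.ascontiguousarray(cube.data.transpose(axes), dtype=dt)
    data_path = header_path.with_suffix(".img")
    disk.tofile(data_path)

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        f"samples = {cube.samples}",
        f"lines = {cube.lines}",
        f"bands = {cube.bands}",
        "header offset = 0",
        f"data type = {_DTYPE_CODES[dt]}",
        f"interleave = {interleave}",
        "byte order = 0",
        f"wavelength = {{ {wl} }}",
    ]
    for key, value in cube.meta.items():
        lines.append(f"{key} = {value}")
    header_path.write_text("\n".join(lines) + "\n")
    return data_path


def nearest_band(wavelengths: np.ndarray, target_nm: float) -> int:
    """Map a wavelength in nm to the nearest band index (ties to the lower band).

    No spectral interpolation is performed: the sensor samples at discrete
    ~4.69 nm centers and interpolating would invent sub-band data.  A target
    more than one band spacing beyond either end of the sensor range is an
    error rather than silently clamped.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength vector")
    lo, hi = wavelengths[0], wavelengths[-1]
    if wavelengths.size > 1:
        spacing_lo = wavelengths[1] - wavelengths[0]
        spacing_hi = wavelengths[-1] - wavelengths[-2]
    else:
        spacing_lo = spacing_hi = 0.0
    if target_nm < lo - spacing_lo or target_nm > hi + spacing_hi:
        raise ValueError(
            f"target out of sensor range: {target_nm} nm outside "
            f"[{lo}, {hi}] ± one band spacing"
        )
    # argmin returns the first minimum, which is the lower index on ties.
    return int(np.argmin(np.abs(wavelengths - target_nm)))


def to_reflectance(cube: HyperspectralCube, panel: PanelRegion) -> ReflectanceCube:
    """Convert raw counts to reflectance against the white reference panel.

    reflectance(pixel, band) = raw(pixel, band) / mean_panel(band), where the
    panel mean is taken spatially over ``panel``.  Any band whose panel mean
    is non-positive cannot be normalized and is reported as a dead band.
    """
    rs, cs = panel.slices()
    if panel.row1 > cube.lines or panel.col1 > cube.samples:
        raise ValueError("panel region exceeds image bounds")
    panel_mean = cube.data[rs, cs, :].astype(float).mean(axis=(0, 1))
    if np.any(panel_mean <= 0):
        bad = np.nonzero(panel_mean <= 0)[0]
        raise ValueError(f"dead band in white reference: band(s) {bad.tolist()}")
    refl = cube.data.astype(float) / panel_mean
    return ReflectanceCube(
        data=refl,
        wavelengths=cube.wavelengths,
        white_stats=panel_mean,
        meta=dict(cube.meta),
    )


def band_window_mean(
    refl: ReflectanceCube,
    window: SpectralWindow,
    pixel: tuple[int, int] | None = None,
) -> float | np.ndarray:
    """Mean reflectance over all bands whose centers lie in the closed window.

    With ``pixel=(row, col)`` returns a scalar; without, the full spatial map.
    The window-mean reading of a range like 759.5–797.02 nm follows the
    three-band-index convention of averaging an NIR plateau rather than
    picking a single band.
    """
    idx = window.band_indices(refl.wavelengths)
    if idx.size == 0:
        raise ValueError(
            f"window selects no bands: [{window.lo_nm}, {window.hi_nm}] nm"
        )
    if pixel is not None:
        row, col = pixel
        return float(refl.data[row, col, idx].mean())
    return refl.data[:, :, idx].mean(axis=2)
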