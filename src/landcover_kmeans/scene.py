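"""In-memory containers for multispectral scenes and ground-truth masks.

A scene holds four aligned digital-number (DN) grids — Blue, Green, Red and
Near-Infrared — for a sensor without SWIR bands. DNs are raw, non-negative
sensor counts (no reflectance calibration is applied anywhere in the
toolkit: the classification thresholds are defined on the DN scale).

Background convention: the imaged footprint is usually rotated relative to
the raster grid, leaving a zero-padded frame. A pixel is *background* iff
every band equals the scene's nodata value (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

BAND_NAMES = ("blue", "green", "red", "nir")


def _as_band(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"band {name!r} must be a 2-D grid, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"band {name!r} contains non-finite values")
    if np.any(arr < 0):
        raise ValidationError(f"band {name!r} contains negative digital numbers")
    return arr


@dataclass
class MultispectralScene:
    """Aligned Blue/Green/Red/NIR digital-number grids.

    Parameters
    ----------
    blue, green, red, nir : array-like, shape (height, width)
        Per-band DN grids. Converted to float64; must be finite and >= 0.
    pixel_size_m : float
        Ground sampling distance in meters (0.5 m for the imagery this
        toolkit targets). Pixel area is ``pixel_size_m ** 2``.
    geotransform : tuple of 6 floats, optional
        Affine georeference ``(x0, dx, rx, y0, ry, dy)``; carried through
        I/O untouched, never interpreted.
    nodata_value : float
        DN marking background padding; a pixel is background iff all four
        bands equal this value.
    """

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    nir: np.ndarray
    pixel_size_m: float = 0.5
    geotransform: tuple | None = None
    nodata_value: float = 0.0

    def __post_init__(self) -> None:
        self.blue = _as_band(self.blue, "blue")
        self.green = _as_band(self.green, "green")
        self.red = _as_band(self.red, "red")
        self.nir = _as_band(self.nir, "nir")
        shapes = {b.shape for b in (self.blue, self.green, self.red, self.nir)}
        if len(shapes) != 1:
            raise ValidationError(f"band grids have mismatched shapes: {shapes}")
        if self.pixel_size_m <= 0:
            raise ValidationError("pixel_size_m must be positive")
        if self.geotransform is not None:
            self.geotransform = tuple(float(v) for v in self.geotransform)
            if len(self.geotransform) != 6:
                raise ValidationError("geotransform must have 6 elements")

    @property
    def height(self) -> int:
        return self.nir.shape[0]

    @property
    def width(self) -> int:
        return self.nir.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.nir.shape

    def band(self, name: str) -> np.ndarray:
        if name not in BAND_NAMES:
            raise ValidationError(f"unknown band {name!r}; expected one of {BAND_NAMES}")
        return getattr(self, name)

    def background_mask(self) -> np.ndarray:
        """Boolean grid; True where every band equals ``nodata_value``."""
        nd = self.nodata_value
        return (
            (self.blue == nd) & (self.green == nd) & (self.red == nd) & (self.nir == nd)
        )


@dataclass
class GroundTruthMask:
    """Binary reference raster: 1 = cultivated, 0 = not cultivated."""

    mask: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2:
            raise ValidationError("mask must be a 2-D grid")
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError("mask values must be exactly 0 or 1")
        self.mask = arr.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape
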