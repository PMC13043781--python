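"""Per-pixel spectral indices on digital-number grids.

Eight classical indices are provided. Each is a pure per-pixel map — no
smoothing, masking or clipping. Zero denominators (typically the zero-padded
background, where every band is 0) yield the value 0 and are flagged in the
``degenerate`` mask instead of producing NaN/inf, so downstream clustering
always sees finite features and background pixels naturally sit at index 0.

Two of the printed formulas differ from the forms most common in the
remote-sensing literature and both variants are supported:

* EVI here has no leading gain factor; pass ``gain=2.5`` for the usual form.
* CVI here is NIR / (Red - Green); ``cvi(scene, literature_form=True)``
  computes the usual NIR * Red / Green**2.

NDWI in its traditional form needs a SWIR band, which this sensor does not
record, so :func:`ndwi` always raises; MNDWI (Green vs NIR) is the
SWIR-free stand-in used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UnsupportedBandError
from .scene import MultispectralScene


@dataclass
class IndexParams:
    """Adjustment constants for SAVI and EVI.

    ``L_savi`` is the soil-adjustment factor (0.5 for intermediate
    vegetation cover); EVI uses canopy background ``L_evi`` = 1 and aerosol
    resistance coefficients ``C1`` = 6, ``C2`` = 7.5.
    """

    L_savi: float = 0.5
    L_evi: float = 1.0
    C1: float = 6.0
    C2: float = 7.5


DEFAULT_PARAMS = IndexParams()


@dataclass
class IndexRaster:
    """One per-pixel float index grid.

    ``degenerate`` marks pixels whose denominator was exactly zero; their
    value is 0 by convention. ``valid_range`` is the nominal bound for
    normalized-difference indices (None for unbounded ones such as DVI).
    """

    values: np.ndarray
    name: str
    degenerate: np.ndarray = field(default=None)
    valid_range: tuple | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.values.shape, dtype=bool)
        else:
            self.degenerate = np.asarray(self.degenerate, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _safe_ratio(numerator: np.ndarray, denominator: np.ndarray):
    """num/den with den == 0 mapped to 0; returns (values, degenerate mask)."""
    degenerate = denominator == 0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        values = np.where(degenerate, 0.0, numerator / np.where(degenerate, 1.0, denominator))
    return values, degenerate


def ndvi(scene: MultispectralScene) -> IndexRaster:
    """Normalized Difference Vegetation Index, (NIR - Red)/(NIR + Red)."""
    values, deg = _safe_ratio(scene.nir - scene.red, scene.nir + scene.red)
    return IndexRaster(values, "ndvi", deg, valid_range=(-1.0, 1.0))


def mndwi(scene: MultispectralScene) -> IndexRaster:
    """Modified Normalized Difference Water Index, (Green - NIR)/(Green + NIR)."""
    values, deg = _safe_ratio(scene.green - scene.nir, scene.green + scene.nir)
    return IndexRaster(values, "mndwi", deg, valid_range=(-1.0, 1.0))


def evi(scene: MultispectralScene, params: IndexParams = DEFAULT_PARAMS,
        gain: float = 1.0) -> IndexRaster:
    """Enhanced Vegetation Index.

    gain * (NIR - Red) / (NIR + C1*Red - C2*Blue + L); the default gain of 1
    matches the tabulated form (the common literature form uses gain 2.5).
    """
    den = scene.nir + params.C1 * scene.red - params.C2 * scene.blue + params.L_evi
    values, deg = _safe_ratio(scene.nir - scene.red, den)
    return IndexRaster(gain * values, "evi", deg)


def savi(scene: MultispectralScene, params: IndexParams = DEFAULT_PARAMS) -> IndexRaster:
    """Soil Adjusted Vegetation Index, (NIR - Red)/(NIR + Red + L) * (1 + L)."""
    values, deg = _safe_ratio(scene.nir - scene.red, scene.nir + scene.red + params.L_savi)
    return IndexRaster(values * (1.0 + params.L_savi), "savi", deg)


def gci(scene: MultispectralScene) -> IndexRaster:
    """Green Chlorophyll Index, NIR/Green - 1."""
    ratio, deg = _safe_ratio(scene.nir, scene.green)
    return IndexRaster(np.where(deg, 0.0, ratio - 1.0), "gci", deg)


def cvi(scene: MultispectralScene, literature_form: bool = False) -> IndexRaster:
    """Chlorophyll Vegetation Index.

    Default: NIR / (Red - Green). With ``literature_form=True``:
    NIR * Red / Green**2.
    """
    if literature_form:
        values, deg = _safe_ratio(scene.nir * scene.red, scene.green ** 2)
    else:
        values, deg = _safe_ratio(scene.nir, scene.red - scene.green)
    return IndexRaster(values, "cvi", deg)


def dvi(scene: MultispectralScene) -> IndexRaster:
    """Difference Vegetation Index, NIR - Red."""
    return IndexRaster(scene.nir - scene.red, "dvi")


def ndwi(scene: MultispectralScene) -> IndexRaster:
    """Normalized Difference Water Index, (NIR - SWIR)/(NIR + SWIR).

    Always raises: the 4-band sensor carries no SWIR band. Use MNDWI.
    """
    raise UnsupportedBandError(
        "NDWI requires a SWIR band, which this 4-band (B/G/R/NIR) sensor lacks; "
        "use mndwi() instead"
    )


INDEX_FUNCTIONS = {
    "ndvi": ndvi, "mndwi": mndwi, "evi": evi, "savi": savi,
    "gci": gci, "cvi": cvi, "dvi": dvi, "ndwi": ndwi,
}


def compute_index(scene: MultispectralScene, name: str, **kwargs) -> IndexRaster:
    """Compute an index by name (one of INDEX_FUNCTIONS)."""
    try:
        fn = INDEX_FUNCTIONS[name.lower()]
    except KeyError:
        raise UnsupportedBandError(f"unknown index {name!r}") from None
    return fn(scene, **kwargs)
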