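"""Raster I/O: multiband scenes, binary masks and three-class label maps.

Files are plain multi-page TIFFs (one page per band, row-major, origin
top-left). Scene metadata — pixel size, the optional affine geotransform
and the nodata value — travels in the TIFF ImageDescription tag as JSON,
so write→read round-trips are lossless.

Band order inside a file is deliberately an *explicit* argument everywhere:
nothing is guessed from metadata, because a silent RGB/BGR mix-up corrupts
every index downstream.
"""

from __future__ import annotations

import json
import os

import numpy as np
import tifffile
from PIL import Image

from .classify import BACKGROUND, CROPS, SOIL, ClassMap
from .exceptions import BandConfigurationError, RasterFormatError, ValidationError
from .scene import BAND_NAMES, GroundTruthMask, MultispectralScene

DEFAULT_BAND_ORDER = ("blue", "green", "red", "nir")

# color-composite palette: white = background, brown = soil, green = crops
CLASS_PALETTE = {BACKGROUND: (255, 255, 255), SOIL: (139, 69, 19), CROPS: (0, 128, 0)}


def _read_pages(path) -> tuple[np.ndarray, dict]:
    if not os.path.exists(path):
        raise IOError(f"raster file not found: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            desc = tif.pages[0].description or ""
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"could not read raster {path}: {exc}") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    if arr.ndim == 2:
        arr = arr[None, :, :]
    elif arr.ndim == 3 and arr.shape[-1] <= 8 < arr.shape[0]:
        # interleaved (H, W, C) layout from other writers
        arr = np.moveaxis(arr, -1, 0)
    elif arr.ndim != 3:
        raise RasterFormatError(f"unsupported raster dimensionality {arr.shape} in {path}")
    return arr, meta


def _meta_description(pixel_size_m, geotransform, nodata_value, band_order=None) -> str:
    meta = {
        "pixel_size_m": pixel_size_m,
        "geotransform": list(geotransform) if geotransform is not None else None,
        "nodata_value": nodata_value,
    }
    if band_order is not None:
        meta["band_order"] = list(band_order)
    return json.dumps(meta)


def read_scene(path, band_order=DEFAULT_BAND_ORDER, nodata_value: float = 0.0,
               pixel_size_m: float | None = None) -> MultispectralScene:
    """Read a multiband raster into a :class:`MultispectralScene`.

    ``band_order`` names each file band in order; it must contain "nir" and
    may name any subset of {blue, green, red, nir}. Bands not named default
    to zero grids (a 3-band product without blue, say, can still drive the
    NIR/NDVI classifiers that do not use blue).
    """
    band_order = tuple(band_order)
    unknown = set(band_order) - set(BAND_NAMES)
    if unknown:
        raise BandConfigurationError(f"unknown band names in band_order: {sorted(unknown)}")
    if len(set(band_order)) != len(band_order):
        raise BandConfigurationError("band_order contains duplicate names")
    if "nir" not in band_order:
        raise BandConfigurationError("band_order must include 'nir'")

    arr, meta = _read_pages(path)
    if arr.shape[0] < len(band_order):
        raise RasterFormatError(
            f"raster has {arr.shape[0]} band(s) but band_order names {len(band_order)}"
        )
    bands = {name: arr[i].astype(np.float64) for i, name in enumerate(band_order)}
    for name in BAND_NAMES:
        bands.setdefault(name, np.zeros(arr.shape[1:], dtype=np.float64))

    gt = meta.get("geotransform")
    return MultispectralScene(
        blue=bands["blue"], green=bands["green"], red=bands["red"], nir=bands["nir"],
        pixel_size_m=pixel_size_m if pixel_size_m is not None else meta.get("pixel_size_m", 0.5),
        geotransform=tuple(gt) if gt else None,
        nodata_value=nodata_value,
    )


def write_scene(scene: MultispectralScene, path, band_order=DEFAULT_BAND_ORDER) -> None:
    """Write a scene as a multi-page float32 TIFF, one page per band."""
    band_order = tuple(band_order)
    data = np.stack([scene.band(name) for name in band_order]).astype(np.float32)
    tifffile.imwrite(
        path, data, photometric="minisblack",
        description=_meta_description(scene.pixel_size_m, scene.geotransform,
                                      scene.nodata_value, band_order),
    )


def read_mask(path, threshold: float = 0.0) -> GroundTruthMask:
    """Read a single-band raster and binarize it: value > threshold -> 1."""
    arr, _ = _read_pages(path)
    if arr.shape[0] != 1:
        raise RasterFormatError(f"mask raster must be single-band, got {arr.shape[0]} bands")
    return GroundTruthMask((arr[0] > threshold).astype(np.uint8))


def write_mask(mask: GroundTruthMask, path) -> None:
    tifffile.imwrite(path, mask.mask.astype(np.uint8), photometric="minisblack")


def write_classmap(classmap: ClassMap, path, color_path=None) -> None:
    """Write a class map as a single-band uint8 raster of label codes 0/1/2.

    If ``color_path`` is given, additionally write an RGB composite using
    the fixed white/brown/green palette.
    """
    labels = np.asarray(classmap.labels)
    if not np.isin(labels, (BACKGROUND, SOIL, CROPS)).all():
        raise ValidationError("class map contains labels outside {0, 1, 2}")
    tifffile.imwrite(
        path, labels.astype(np.uint8), photometric="minisblack",
        description=json.dumps({"provenance": classmap.provenance}),
    )
    if color_path is not None:
        rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
        for code, color in CLASS_PALETTE.items():
            rgb[labels == code] = color
        Image.fromarray(rgb, mode="RGB").save(color_path)


def read_classmap(path) -> ClassMap:
    arr, meta = _read_pages(path)
    if arr.shape[0] != 1:
        raise RasterFormatError(f"class-map raster must be single-band, got {arr.shape[0]} bands")
    labels = arr[0]
    if not np.isin(labels, (BACKGROUND, SOIL, CROPS)).all():
        raise ValidationError("class-map raster contains labels outside {0, 1, 2}")
    return ClassMap(labels=labels.astype(np.uint8), provenance=meta.get("provenance", {}))
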