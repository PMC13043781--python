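"""Area accounting and relative-error scoring against ground truth.

Two quantities drive the study's accuracy criterion:

* cultivated-area percentage = (cultivated pixels / total pixels) * 100,
  optionally excluding the zero-padded background from the denominator;
* relative error = |detected - actual| / actual * 100, comparing a
  classifier's detected cultivated percentage with the reference
  (ground-truth) percentage.

Percentages are kept at full precision internally; rounding to two decimal
places happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import BACKGROUND, CROPS, CLASS_NAMES, ClassMap
from .exceptions import ValidationError
from .scene import GroundTruthMask


def cultivated_percentage(classmap: ClassMap, include_background: bool = True) -> float:
    """Percent of pixels labeled crops.

    With ``include_background=True`` (default) the denominator is every
    pixel in the map; otherwise background pixels are excluded.
    """
    labels = classmap.labels
    if labels.size == 0:
        raise ValidationError("empty class map")
    crops = int(np.sum(labels == CROPS))
    if include_background:
        total = labels.size
    else:
        total = int(np.sum(labels != BACKGROUND))
    if total == 0:
        raise ValidationError("no pixels in denominator (all background)")
    return 100.0 * crops / total


def mask_percentage(mask: GroundTruthMask, background: np.ndarray | None = None,
                    include_background: bool = True) -> float:
    """Percent of mask pixels set to 1, under the same denominator
    convention as :func:`cultivated_percentage`.

    ``background`` (a boolean grid, e.g. ``scene.background_mask()`` or
    ``classmap.labels == BACKGROUND``) is required only when excluding
    background from the denominator.
    """
    m = mask.mask
    if m.size == 0:
        raise ValidationError("empty mask")
    if include_background:
        total = m.size
    else:
        if background is None:
            raise ValidationError(
                "include_background=False requires a background grid")
        background = np.asarray(background, dtype=bool)
        if background.shape != m.shape:
            raise ValidationError(
                f"dimension mismatch: mask {m.shape} vs background {background.shape}")
        total = int(np.sum(~background))
        if total == 0:
            raise ValidationError("no pixels in denominator (all background)")
    return 100.0 * int(m.sum()) / total


def relative_error(detected_percent: float, actual_percent: float) -> float:
    """|detected - actual| / actual * 100 (the study's error criterion)."""
    if actual_percent <= 0:
        raise ValidationError("actual_percent must be positive")
    return abs(detected_percent - actual_percent) / actual_percent * 100.0


def agreement_table(classmap: ClassMap, mask: GroundTruthMask) -> dict:
    """2x2 pixel agreement counts between predicted crops and the mask.

    Returns keys ``crops_cultivated`` (predicted crops, mask 1),
    ``crops_uncultivated``, ``noncrops_cultivated``, ``noncrops_uncultivated``;
    the four counts sum to the total pixel count.
    """
    if classmap.shape != mask.shape:
        raise ValidationError(
            f"dimension mismatch: classmap {classmap.shape} vs mask {mask.shape}")
    pred = classmap.labels == CROPS
    truth = mask.mask == 1
    return {
        "crops_cultivated": int(np.sum(pred & truth)),
        "crops_uncultivated": int(np.sum(pred & ~truth)),
        "noncrops_cultivated": int(np.sum(~pred & truth)),
        "noncrops_uncultivated": int(np.sum(~pred & ~truth)),
    }


@dataclass
class AreaReport:
    """Per-class pixel accounting plus the detected/reference comparison.

    ``pixel_area_m2`` is the square of the ground sampling distance
    (0.25 m^2 at 0.5 m GSD); ``cultivated_area_m2`` converts the crops
    count to square meters. ``reference_percent`` and
    ``relative_error_percent`` are present only when a ground-truth mask
    was supplied.
    """

    class_pixel_counts: dict
    pixel_area_m2: float
    cultivated_percent: float
    cultivated_area_m2: float
    reference_percent: float | None = None
    relative_error_percent: float | None = None

    def to_dict(self) -> dict:
        d = {
            "class_pixel_counts": dict(self.class_pixel_counts),
            "pixel_area_m2": self.pixel_area_m2,
            "cultivated_area_m2": self.cultivated_area_m2,
            "cultivated_percent": round(self.cultivated_percent, 2),
        }
        if self.reference_percent is not None:
            d["reference_percent"] = round(self.reference_percent, 2)
            d["relative_error_percent"] = round(self.relative_error_percent, 2)
        return d


def area_report(classmap: ClassMap, mask: GroundTruthMask | None = None,
                pixel_size_m: float = 0.5, include_background: bool = True) -> AreaReport:
    """Summarize a class map (and optionally score it against a mask)."""
    counts = classmap.class_counts()
    detected = cultivated_percentage(classmap, include_background=include_background)
    pixel_area = pixel_size_m ** 2
    reference = error = None
    if mask is not None:
        if mask.shape != classmap.shape:
            raise ValidationError(
                f"dimension mismatch: classmap {classmap.shape} vs mask {mask.shape}")
        background = classmap.labels == BACKGROUND
        reference = mask_percentage(mask, background=background,
                                    include_background=include_background)
        error = relative_error(detected, reference)
    return AreaReport(
        class_pixel_counts=counts,
        pixel_area_m2=pixel_area,
        cultivated_percent=detected,
        cultivated_area_m2=counts[CLASS_NAMES[CROPS]] * pixel_area,
        reference_percent=reference,
        relative_error_percent=error,
    )
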