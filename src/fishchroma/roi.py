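"""Dorsal thumbnail extraction, stripe masking and mean CIELAB measurement.

The protocol crops a 530 x 53 px strip along the dorsal axis, thresholds the
green colour plane so only the light "coloured section" between the dark
stripes is kept, and reports the mean L*/a*/b* of the kept pixels
(per-pixel conversion, then averaging).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .colour import CorrectionModel, LabTriple, linear_rgb_to_lab, srgb_decode

__all__ = ["ROISpec", "ColourMeasurement", "extract_thumbnail", "stripe_mask", "measure_colour"]

#: Minimum number of kept pixels for a reliable mean colour.
MIN_PIXELS = 50


@dataclass
class ROISpec:
    """Rectangular measurement strip: top-left (x, y), width x height px."""

    x: int
    y: int
    width: int = 530
    height: int = 53

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI dimensions must be positive")
        if self.width < self.height:
            raise ValueError("ROI must be landscape (width >= height) along the dorsal axis")

    def slices(self):
        return slice(self.y, self.y + self.height), slice(self.x, self.x + self.width)


@dataclass
class ColourMeasurement:
    """Mean CIELAB of the masked coloured-section pixels, with audit fields."""

    mean_lab: LabTriple
    n_pixels_used: int
    mask_fraction: float
    threshold_value: float
    gain: float = 1.0
    reliable: bool = True


def extract_thumbnail(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Exact pixel crop of the ROI; no resampling."""
    h, w = image.shape[:2]
    if roi.x < 0 or roi.y < 0 or roi.x + roi.width > w or roi.y + roi.height > h:
        raise ValueError(f"ROI {roi} outside image of shape {(h, w)}")
    ys, xs = roi.slices()
    return image[ys, xs].copy()


def stripe_mask(thumbnail: np.ndarray):
    """Mask out the dark stripes by Otsu thresholding the green plane.

    Pixels strictly above the threshold (the light inter-stripe regions) are
    kept.  A constant thumbnail keeps every pixel (with a warning) since no
    threshold separates it.

    Returns ``(mask, threshold_value)``.
    """
    green = np.asarray(thumbnail)[..., 1]
    vals = np.unique(green)
    if vals.size < 2:
        warnings.warn("constant thumbnail: keeping all pixels", stacklevel=2)
        return np.ones(green.shape, dtype=bool), float(vals[0])
    thr = threshold_otsu(green)
    return green > thr, float(thr)


def measure_colour(thumbnail: np.ndarray, mask: np.ndarray,
                   correction: CorrectionModel | None = None,
                   exposure_gain: float = 1.0,
                   threshold_value: float = float("nan")) -> ColourMeasurement:
    """Mean CIELAB over the masked pixels of an 8-bit (or float) thumbnail.

    Each kept pixel is sRGB-decoded, exposure-scaled, matrix-corrected and
    converted to CIELAB; the arithmetic mean of L*, a*, b* over kept pixels
    is returned.  Fewer than 50 kept pixels flags the measurement unreliable.
    """
    thumb = np.asarray(thumbnail)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != thumb.shape[:2]:
        raise ValueError("mask shape must match thumbnail")
    n_total = mask.size
    n_used = int(mask.sum())
    if n_used == 0:
        raise ValueError("empty mask")
    reliable = n_used >= MIN_PIXELS
    if not reliable:
        warnings.warn(f"only {n_used} pixels kept; measurement unreliable", stacklevel=2)

    px = thumb[mask].astype(float)
    if thumb.dtype == np.uint8:
        px = px / 255.0
    elif thumb.dtype == np.uint16:
        px = px / 65535.0
    linear = srgb_decode(px) * exposure_gain
    if correction is not None:
        linear = linear * correction.gain @ correction.matrix.T
    lab = linear_rgb_to_lab(np.clip(linear, 0.0, 1.0))
    # sort before summing so the mean is bit-identical under pixel reordering
    mean = np.sort(lab, axis=0).mean(axis=0)
    return ColourMeasurement(
        mean_lab=LabTriple(float(mean[0]), float(mean[1]), float(mean[2])),
        n_pixels_used=n_used,
        mask_fraction=n_used / n_total,
        threshold_value=threshold_value,
        gain=float(exposure_gain),
        reliable=reliable,
    )
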