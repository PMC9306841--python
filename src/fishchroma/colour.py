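"""Colour-space mathematics and photographic calibration.

The measurement chain mirrors a linear photographic workflow: sRGB-encoded
pixel values are decoded to linear RGB, exposure-normalised against the known
white background the fish lies on, multiplied by a chart-fitted 3x3 colour
correction matrix, and finally converted through CIE XYZ to CIELAB (D65).
All conversions are exact inverses of their counterparts.

CIELAB axes follow the usual convention: L* is lightness (0-100), a* runs
green(-) to red(+), b* runs blue(-) to yellow(+).  Reduction in b* is the
"blueing" response of stressed mackerel skin that the rest of the package
quantifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "LabTriple",
    "XYZTriple",
    "CorrectionModel",
    "D65_WHITE",
    "srgb_decode",
    "srgb_encode",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "xyz_to_lab",
    "lab_to_xyz",
    "lab_to_linear_rgb",
    "linear_rgb_to_lab",
    "delta_e",
    "fit_correction",
    "exposure_normalize",
]


class LabTriple(NamedTuple):
    """One CIE L*/a*/b* measurement."""

    L: float
    a: float
    b: float


class XYZTriple(NamedTuple):
    """CIE tristimulus values, normalised so the white point has Y = 100."""

    X: float
    Y: float
    Z: float


#: D65 reference white (2 degree observer), Y scaled to 100.
D65_WHITE = XYZTriple(95.047, 100.0, 108.883)

# sRGB (IEC 61966-2-1) linear RGB -> XYZ, D65 primaries, scaled to Y=100.
_RGB2XYZ = 100.0 * np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ2RGB = np.linalg.inv(_RGB2XYZ)


def srgb_decode(encoded):
    """sRGB transfer function: encoded [0,1] -> linear [0,1] (vectorised)."""
    v = np.clip(np.asarray(encoded, dtype=float), 0.0, 1.0)
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def srgb_encode(linear):
    """Exact inverse of :func:`srgb_decode`."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    return np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1.0 / 2.4) - 0.055)


def linear_rgb_to_xyz(rgb_linear):
    """Linear sRGB -> XYZ (D65).  Accepts (..., 3) arrays."""
    rgb = np.asarray(rgb_linear, dtype=float)
    return rgb @ _RGB2XYZ.T


def xyz_to_linear_rgb(xyz):
    """XYZ (D65) -> linear sRGB; inverse of :func:`linear_rgb_to_xyz`."""
    x = np.asarray(xyz, dtype=float)
    return x @ _XYZ2RGB.T


# CIE f(t) threshold: (6/29)^3
_EPS = (6.0 / 29.0) ** 3
_KAPPA = (29.0 / 6.0) ** 2 / 3.0  # slope of the linear segment


def _f_cie(t):
    t = np.asarray(t, dtype=float)
    return np.where(t > _EPS, np.cbrt(t), _KAPPA * t + 4.0 / 29.0)


def _f_cie_inv(ft):
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > 6.0 / 29.0, ft ** 3, (ft - 4.0 / 29.0) / _KAPPA)


def xyz_to_lab(xyz, white: XYZTriple = D65_WHITE):
    """XYZ -> CIELAB relative to ``white``.  Accepts (..., 3) arrays."""
    w = np.asarray(white, dtype=float)
    if np.any(w <= 0):
        raise ValueError("white point components must be strictly positive")
    x = np.asarray(xyz, dtype=float) / w
    fx, fy, fz = _f_cie(x[..., 0]), _f_cie(x[..., 1]), _f_cie(x[..., 2])
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return np.stack([L, a, b], axis=-1)


def lab_to_xyz(lab, white: XYZTriple = D65_WHITE):
    """CIELAB -> XYZ; inverse of :func:`xyz_to_lab`."""
    w = np.asarray(white, dtype=float)
    if np.any(w <= 0):
        raise ValueError("white point components must be strictly positive")
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_f_cie_inv(fx), _f_cie_inv(fy), _f_cie_inv(fz)], axis=-1)
    return xyz * w


def lab_to_linear_rgb(lab, white: XYZTriple = D65_WHITE):
    """CIELAB -> linear sRGB (may leave [0,1] for out-of-gamut colours)."""
    return xyz_to_linear_rgb(lab_to_xyz(lab, white))


def linear_rgb_to_lab(rgb_linear, white: XYZTriple = D65_WHITE):
    """Linear sRGB -> CIELAB."""
    return xyz_to_lab(linear_rgb_to_xyz(rgb_linear), white)


def delta_e(lab1, lab2):
    """CIE76 colour difference: Euclidean distance in CIELAB."""
    d = np.asarray(lab1, dtype=float) - np.asarray(lab2, dtype=float)
    return np.sqrt(np.sum(d * d, axis=-1))


@dataclass
class CorrectionModel:
    """Chart-fitted colour correction: linear-RGB matrix plus exposure gain.

    ``matrix`` maps measured (camera) linear RGB to reference linear RGB;
    ``gain`` is a scalar exposure multiplier applied before the matrix.
    ``fit_residual`` is the RMS per-channel patch error of the fit.
    """

    matrix: np.ndarray
    gain: float = 1.0
    fit_residual: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("correction matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("correction matrix must be invertible")
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def apply(self, rgb_linear):
        """Apply gain then matrix to (..., 3) linear RGB values."""
        rgb = np.asarray(rgb_linear, dtype=float) * self.gain
        return rgb @ self.matrix.T

    def to_yaml(self, path):
        payload = {
            "matrix": [[float(v) for v in row] for row in self.matrix],
            "gain": float(self.gain),
            "fit_residual": float(self.fit_residual),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            matrix=np.array(payload["matrix"], dtype=float),
            gain=float(payload["gain"]),
            fit_residual=float(payload.get("fit_residual", 0.0)),
            meta=payload.get("meta", {}),
        )


def fit_correction(measured_patches, reference_patches) -> CorrectionModel:
    """Least-squares 3x3 colour correction from chart patch pairs.

    Solves min_M sum ||M m_i - r_i||^2 over patches in linear RGB.  Exposure
    is handled separately (gain initialised at 1); normalise patch exposure
    before calling if the chart and subject images differ in flash output.

    Parameters
    ----------
    measured_patches, reference_patches
        (n, 3) arrays of linear-RGB patch means; n >= 3 and the measured set
        must span RGB space (rank 3), which a 24-patch chart always does.
    """
    m = np.asarray(measured_patches, dtype=float)
    r = np.asarray(reference_patches, dtype=float)
    if m.shape != r.shape or m.ndim != 2 or m.shape[1] != 3:
        raise ValueError("patch arrays must both be (n, 3)")
    if m.shape[0] < 3:
        raise ValueError("need at least 3 patch pairs")
    if np.linalg.matrix_rank(m) < 3:
        raise ValueError("rank-deficient patch set: patches are coplanar")
    # M m = r for each row  <=>  m @ M.T = r
    mt, *_ = np.linalg.lstsq(m, r, rcond=None)
    matrix = mt.T
    resid = m @ matrix.T - r
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return CorrectionModel(matrix=matrix, gain=1.0, fit_residual=rms)


def exposure_normalize(image_linear, white_region, reference_white):
    """Scale a linear image so the white-background region hits its reference.

    The "intensity" of the white region is the mean of the green channel's
    linearised values (green tracks luminance closely and matches the green
    plane used for stripe masking).

    Parameters
    ----------
    image_linear : (H, W, 3) float array, linear RGB.
    white_region : (x, y, width, height) rectangle of background pixels.
    reference_white : expected linear green value of the background.

    Returns
    -------
    (scaled_image, gain, saturated) — ``saturated`` is True when the region
    mean is >= 0.99 before scaling, in which case the gain is unreliable.
    """
    img = np.asarray(image_linear, dtype=float)
    x, y, w, h = white_region
    if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > img.shape[1] or y + h > img.shape[0]:
        raise ValueError("white_region outside image bounds")
    region_mean = float(img[y : y + h, x : x + w, 1].mean())
    saturated = region_mean >= 0.99
    if saturated:
        warnings.warn(
            "white region mean >= 0.99: background is clipped, exposure gain unreliable",
            stacklevel=2,
        )
    if region_mean <= 0:
        raise ValueError("white region is black; cannot normalise exposure")
    gain = float(reference_white) / region_mean
    return img * gain, gain, saturated
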