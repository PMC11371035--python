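"""Detector geometry: calibration, center/rotation detection, rectification.

Conventions
-----------
* Images are 2-D arrays indexed ``[row, col]``; a point is ``(x, y)`` with
  ``x`` the column and ``y`` the row, both 0-based floats with pixel centers
  at integer coordinates.
* Rotation angles are in degrees, counterclockwise positive in ``(x, y)``
  array coordinates, normalized to ``(-90, +90]``; they describe the angle of
  the equatorial axis relative to the image row axis.
* The reciprocal coordinate is ``d* = 1/d`` in inverse nanometres (the fiber
  diffraction convention), not ``2*pi/d``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage, signal

from .exceptions import (
    CalibrationError,
    CalibrationRequiredError,
    DegenerateInputError,
    OrientationUndeterminedError,
)

__all__ = [
    "Calibration",
    "PatternFrame",
    "fit_calibration",
    "pixel_to_d",
    "d_to_pixel",
    "find_center",
    "find_rotation",
    "rectify",
    "SILVER_BEHENATE_D_NM",
]

#: Lamellar d-spacing of the silver behenate powder standard (config default,
#: overridable in the settings file).
SILVER_BEHENATE_D_NM = 5.838


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Beam geometry linking detector pixels to d-spacings.

    Parameters
    ----------
    wavelength_nm : float
        X-ray wavelength in nanometres.
    distance_mm : float
        Sample-to-detector distance in millimetres.
    pixel_size_mm : float
        Edge length of a (square) detector pixel in millimetres.
    center : tuple of float
        Beam center ``(cx, cy)`` in fractional pixel coordinates.
    calibrated : bool
        When False, radial positions are reported in pixels and d-spacing
        conversions raise :class:`CalibrationRequiredError`.
    """

    wavelength_nm: float
    distance_mm: float
    pixel_size_mm: float
    center: tuple[float, float] = (0.0, 0.0)
    calibrated: bool = True

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be > 0")
        if self.distance_mm <= 0:
            raise ValueError("distance_mm must be > 0")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be > 0")


@dataclasses.dataclass(frozen=True)
class PatternFrame:
    """Per-image frame of reference: pattern center and equator rotation."""

    center: tuple[float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _normalize_angle(self.rotation))


def _normalize_angle(angle: float) -> float:
    """Map an angle in degrees to the interval (-90, +90]."""
    a = (float(angle) + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


# ---------------------------------------------------------------------------
# pixel <-> d-spacing conversions
# ---------------------------------------------------------------------------

def pixel_to_d(r, cal: Calibration):
    """Convert a radial distance in pixels to a d-spacing in nm.

    Uses the exact Bragg geometry ``d = lambda / (2 sin(theta))`` with
    ``2 theta = atan(r * pixel / distance)``; strictly decreasing in ``r``.
    """
    if not cal.calibrated:
        raise CalibrationRequiredError("d-spacings undefined without calibration")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("radial distance must be > 0")
    two_theta = np.arctan(r * cal.pixel_size_mm / cal.distance_mm)
    d = cal.wavelength_nm / (2.0 * np.sin(0.5 * two_theta))
    return d if d.ndim else float(d)


def d_to_pixel(d, cal: Calibration):
    """Inverse of :func:`pixel_to_d`: d-spacing in nm to radius in pixels."""
    if not cal.calibrated:
        raise CalibrationRequiredError("d-spacings undefined without calibration")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d-spacing must be > 0")
    two_theta = 2.0 * np.arcsin(cal.wavelength_nm / (2.0 * d))
    r = np.tan(two_theta) * cal.distance_mm / cal.pixel_size_mm
    return r if r.ndim else float(r)


def d_star(d):
    """Reciprocal coordinate d* = 1/d (nm^-1)."""
    return 1.0 / np.asarray(d, dtype=float)


# ---------------------------------------------------------------------------
# center detection
# ---------------------------------------------------------------------------

def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Sub-sample offset of a parabola through three equally spaced samples."""
    denom = cm - 2.0 * c0 + cp
    if denom == 0:
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def find_center(image: np.ndarray) -> tuple[float, float]:
    """Locate the pattern center by Friedel (180 degree) autocorrelation.

    The full self-convolution of the image equals its cross-correlation with
    its own 180-degree rotation; the correlation peak sits at twice the
    center of symmetry.  The peak is refined to sub-pixel accuracy by
    parabolic interpolation along each axis.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    if np.ptp(img) == 0:
        raise DegenerateInputError("flat image has no center of symmetry")
    work = img - img.mean()
    conv = signal.fftconvolve(work, work, mode="full")
    py, px = np.unravel_index(np.argmax(conv), conv.shape)
    dy = dx = 0.0
    if 0 < py < conv.shape[0] - 1:
        dy = _parabolic_offset(conv[py - 1, px], conv[py, px], conv[py + 1, px])
    if 0 < px < conv.shape[1] - 1:
        dx = _parabolic_offset(conv[py, px - 1], conv[py, px], conv[py, px + 1])
    return ((px + dx) / 2.0, (py + dy) / 2.0)


# ---------------------------------------------------------------------------
# rotation detection
# ---------------------------------------------------------------------------

def _orientation_weights(img: np.ndarray) -> np.ndarray:
    """Background-referenced non-negative weights for orientation statistics."""
    return np.clip(img - np.median(img), 0.0, None)


def find_rotation(
    image: np.ndarray,
    center: tuple[float, float],
    method: str = "azimuthal",
    significance: float = 5.0,
) -> float:
    """Estimate the equator angle (degrees, in (-90, 90]) about ``center``.

    Two estimators are available:

    ``azimuthal``
        Intensity-weighted azimuthal histogram (1 degree bins, orientation
        folded modulo 180), maximum refined by a local circular centroid.
    ``second_moment``
        Principal axis of the intensity-weighted second-moment tensor.

    Raises :class:`OrientationUndeterminedError` when no direction exceeds
    the histogram mean by ``significance`` standard deviations (the caller
    may then default to 0 degrees).
    """
    img = np.asarray(image, dtype=np.float64)
    cx, cy = center
    yy, xx = np.indices(img.shape)
    dx = xx - cx
    dy = yy - cy
    w = _orientation_weights(img)
    if w.sum() == 0:
        raise DegenerateInputError("image carries no intensity above background")

    phi = np.degrees(np.arctan2(dy, dx)) % 180.0
    hist, _ = np.histogram(phi, bins=180, range=(0.0, 180.0), weights=w)
    mean, std = hist.mean(), hist.std()
    if std == 0 or hist.max() < mean + significance * std:
        raise OrientationUndeterminedError("pattern is isotropic")

    if method == "second_moment":
        sxx = np.sum(w * dx * dx)
        syy = np.sum(w * dy * dy)
        sxy = np.sum(w * dx * dy)
        angle = 0.5 * math.degrees(math.atan2(2.0 * sxy, sxx - syy))
        return _normalize_angle(angle)
    if method != "azimuthal":
        raise ValueError(f"unknown orientation method: {method!r}")

    k = int(np.argmax(hist))
    # local circular centroid over +/-3 bins around the maximum
    offsets = np.arange(-3, 4)
    vals = hist[(k + offsets) % 180]
    vals = np.clip(vals - vals.min(), 0.0, None)
    if vals.sum() > 0:
        k = k + float(np.sum(offsets * vals) / vals.sum())
    return _normalize_angle(k + 0.5)  # bin k spans [k, k+1) degrees


# ---------------------------------------------------------------------------
# calibration from a powder ring
# ---------------------------------------------------------------------------

def fit_calibration(
    ring_image: np.ndarray,
    d_spacing_nm: float,
    wavelength_nm: float,
    pixel_size_mm: float,
    min_radius: float = 5.0,
) -> Calibration:
    """Solve the camera geometry from one powder ring of known d-spacing.

    The beam center comes from Friedel autocorrelation of the ring image; the
    ring radius ``R`` is the sub-pixel peak of the azimuthally averaged
    radial profile.  The camera length follows from
    ``R * pixel / L = tan(2 theta)`` with ``2 theta = 2 asin(lambda / 2d)``
    (silver behenate being the usual standard).
    """
    if d_spacing_nm <= 0:
        raise ValueError("d_spacing_nm must be > 0")
    img = np.asarray(ring_image, dtype=np.float64)
    center = find_center(img)
    cx, cy = center

    yy, xx = np.indices(img.shape)
    r = np.hypot(xx - cx, yy - cy)
    rbin = np.round(r).astype(np.intp)  # bin k spans [k-0.5, k+0.5)
    nbins = int(rbin.max()) + 1
    tot = np.bincount(rbin.ravel(), weights=img.ravel(), minlength=nbins)
    cnt = np.bincount(rbin.ravel(), minlength=nbins)
    profile = np.where(cnt > 0, tot / np.maximum(cnt, 1), 0.0)

    lo = int(min_radius)
    # only annuli with enough pixels for a stable azimuthal mean
    usable = np.flatnonzero((np.arange(nbins) >= lo) & (cnt >= 50))
    if usable.size < 5:
        raise CalibrationError("image too small to hold a ring")
    peak = int(usable[np.argmax(profile[usable])])
    if peak <= lo or peak >= nbins - 1:
        raise CalibrationError("no powder ring detected above the noise floor")
    base = np.median(profile[usable])
    robust_sigma = 1.4826 * np.median(np.abs(profile[usable] - base))
    if profile[peak] - base < 5.0 * max(robust_sigma, 1e-12):
        raise CalibrationError("no powder ring detected above the noise floor")
    dr = _parabolic_offset(profile[peak - 1], profile[peak], profile[peak + 1])
    ring_radius = peak + dr

    two_theta = 2.0 * math.asin(wavelength_nm / (2.0 * d_spacing_nm))
    distance_mm = ring_radius * pixel_size_mm / math.tan(two_theta)
    return Calibration(
        wavelength_nm=wavelength_nm,
        distance_mm=distance_mm,
        pixel_size_mm=pixel_size_mm,
        center=center,
        calibrated=True,
    )


# ---------------------------------------------------------------------------
# rectification
# ---------------------------------------------------------------------------

def rectify(
    image: np.ndarray,
    frame: PatternFrame,
    fill_value: float = -1.0,
    recenter: bool = False,
) -> tuple[np.ndarray, PatternFrame]:
    """Rotate the pattern so its equator is horizontal.

    The image is rotated by ``-frame.rotation`` about ``frame.center`` with
    bilinear interpolation; pixels falling outside the original footprint are
    filled with ``fill_value`` (choose it below the mask threshold so every
    downstream stage excludes them).  With ``recenter=True`` the pattern is
    additionally translated so the center lands on the pixel-boundary
    crossing nearest the image middle.  Returns the image and the updated
    frame (rotation 0).
    """
    img = np.asarray(image, dtype=np.float64)
    cx, cy = frame.center
    h, w = img.shape

    out_cx, out_cy = cx, cy
    if recenter:
        # pixel boundaries sit at half-integers; pick the one nearest middle
        out_cx = math.floor((w - 1) / 2.0) + 0.5
        out_cy = math.floor((h - 1) / 2.0) + 0.5

    theta = math.radians(frame.rotation)
    if theta == 0.0 and (out_cx, out_cy) == (cx, cy):
        return img.astype(np.float32), PatternFrame((cx, cy), 0.0)

    # output (x,y) maps to input via rotation by +theta about the center
    c, s = math.cos(theta), math.sin(theta)
    # matrix in (row, col) = (y, x) ordering
    mat = np.array([[c, s], [-s, c]])
    out_center = np.array([out_cy, out_cx])
    in_center = np.array([cy, cx])
    offset = in_center - mat @ out_center
    out = ndimage.affine_transform(
        img, mat, offset=offset, order=1, mode="constant", cval=fill_value
    )
    return out.astype(np.float32), PatternFrame((out_cx, out_cy), 0.0)
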