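"""Box-integrated 1-D projections and peak measurement.

A 2-D pattern is reduced to a 1-D trace by summing intensity across the
width of a box aligned with the meridian, the equator, or an arbitrary
direction.  Peaks in the trace are measured two ways: by nonlinear
least-squares Gaussian fits (best for integrated intensity) and by the
centroid of the top half of the peak (less sensitive to noise and to peak
shape changes, so better for small spacing changes), with a triangular
height-times-FWHM area for cross-checking.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import lmfit
from scipy import ndimage

from .exceptions import GeometryError

__all__ = [
    "Box",
    "Trace",
    "PeakMeasurement",
    "project_box",
    "convex_hull_baseline",
    "fit_peaks_gaussian",
    "centroid_top_half",
    "measure_distance",
]


@dataclasses.dataclass(frozen=True)
class Box:
    """An integration box.

    ``kind`` is ``meridian_axial`` (project onto the vertical axis),
    ``equator_axial`` (onto the horizontal axis) or ``oriented`` (onto the
    axis at ``angle`` degrees).  ``anchor`` is the box center ``(x, y)`` in
    pixels — trace coordinates are signed distances from it along the
    projection axis; an oriented box need not pass through the pattern
    center.  ``length`` runs along the projection axis, ``width`` across it.
    """

    kind: str
    anchor: tuple[float, float]
    length: int
    width: int
    angle: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("meridian_axial", "equator_axial", "oriented"):
            raise ValueError(f"unknown box kind: {self.kind!r}")
        if self.width < 1 or self.length < 1:
            raise ValueError("box length and width must be >= 1")


@dataclasses.dataclass
class Trace:
    """A 1-D projection: strictly increasing coordinates plus intensities."""

    coordinate: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.coordinate = np.asarray(self.coordinate, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.coordinate.shape != self.intensity.shape:
            raise ValueError("coordinate and intensity lengths differ")
        if np.any(np.diff(self.coordinate) <= 0):
            raise ValueError("coordinate must be strictly increasing")


@dataclasses.dataclass
class PeakMeasurement:
    """Dual position/intensity measures for one peak.

    ``centroid`` is the top-half centroid position; ``triangular_area`` is
    ``height * halfwidth`` (a triangle of base twice the FWHM).  The Gaussian
    fields are filled when a fit was run, else None.
    """

    centroid: float
    height: float
    halfwidth: float
    triangular_area: float
    gauss_center: float | None = None
    gauss_area: float | None = None
    gauss_sigma: float | None = None
    flagged: bool = False


def project_box(
    image: np.ndarray,
    box: Box,
    sentinel_threshold: float | None = None,
) -> Trace:
    """Integrate a box across its width into a 1-D trace.

    Pixels below ``sentinel_threshold`` (masked regions, detector gaps,
    rectification fill) are excluded, and each axial position is
    renormalized to the nominal width so gaps do not bite into the trace.
    Oriented boxes sample rotated rows with bilinear interpolation.
    """
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    ax, ay = box.anchor

    if box.kind == "oriented":
        theta = math.radians(box.angle)
        ca, sa = math.cos(theta), math.sin(theta)
        t = np.arange(box.length) - (box.length - 1) / 2.0
        s = np.arange(box.width) - (box.width - 1) / 2.0
        tt, ss = np.meshgrid(t, s, indexing="ij")
        xs = ax + tt * ca - ss * sa
        ys = ay + tt * sa + ss * ca
        inside = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
        if not inside.any():
            raise GeometryError("oriented box lies fully outside the image")
        vals = ndimage.map_coordinates(img, [ys, xs], order=1, cval=np.nan)
        valid = inside & np.isfinite(vals)
        coord = t
    else:
        if box.kind == "equator_axial":
            x0 = int(round(ax - (box.length - 1) / 2.0))
            y0 = int(round(ay - (box.width - 1) / 2.0))
            cols = np.arange(x0, x0 + box.length)
            rows = np.arange(y0, y0 + box.width)
            keep_c = (cols >= 0) & (cols < w)
            keep_r = (rows >= 0) & (rows < h)
            if not keep_c.any() or not keep_r.any():
                raise GeometryError("box lies fully outside the image")
            sub = img[np.ix_(rows[keep_r], cols[keep_c])]
            vals = sub.T  # axial positions along rows of vals
            coord = cols[keep_c] - ax
        else:  # meridian_axial
            x0 = int(round(ax - (box.width - 1) / 2.0))
            y0 = int(round(ay - (box.length - 1) / 2.0))
            cols = np.arange(x0, x0 + box.width)
            rows = np.arange(y0, y0 + box.length)
            keep_c = (cols >= 0) & (cols < w)
            keep_r = (rows >= 0) & (rows < h)
            if not keep_c.any() or not keep_r.any():
                raise GeometryError("box lies fully outside the image")
            vals = img[np.ix_(rows[keep_r], cols[keep_c])]
            coord = rows[keep_r] - ay
        valid = np.isfinite(vals)

    if sentinel_threshold is not None:
        valid = valid & (vals >= sentinel_threshold)
    nominal = box.width
    n_valid = valid.sum(axis=1)
    summed = np.where(valid, vals, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(n_valid > 0, summed * (nominal / np.maximum(n_valid, 1)), 0.0)
    return Trace(coord, intensity)


def _lower_hull_vertices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Indices of the lower convex hull vertices (Andrew monotone chain)."""
    hull: list[int] = []
    for i in range(len(x)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j -> i
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def convex_hull_baseline(
    trace: Trace,
    rmin: float | None = None,
    rmax: float | None = None,
) -> np.ndarray:
    """Model-free baseline: the lower convex hull of the trace.

    Within ``[rmin, rmax]`` the baseline is the lower convex envelope of the
    points, evaluated by linear interpolation between hull vertices; outside
    the range it equals the trace (zero residual).  The baseline never
    exceeds the trace and touches it at the hull vertices.
    """
    x, y = trace.coordinate, trace.intensity
    lo = x[0] if rmin is None else rmin
    hi = x[-1] if rmax is None else rmax
    sel = (x >= lo) & (x <= hi)
    if sel.sum() < 3:
        raise ValueError("convex hull baseline needs at least 3 points in range")
    xs, ys = x[sel], y[sel]
    verts = _lower_hull_vertices(xs, ys)
    baseline = np.array(y, dtype=np.float64, copy=True)
    baseline[sel] = np.interp(xs, xs[verts], ys[verts])
    return baseline


@dataclasses.dataclass
class GaussPeakFit:
    """One fitted Gaussian component: center/area/sigma plus a success flag."""

    center: float
    area: float
    sigma: float
    flagged: bool = False


def fit_peaks_gaussian(
    trace: Trace,
    initial_centers,
    background: str = "hull",
    n_background_gaussians: int = 2,
) -> list[GaussPeakFit]:
    """Fit a sum of Gaussians to the trace by nonlinear least squares.

    The diffuse background under the peaks is removed first by the convex
    hull (``background="hull"``) or modelled in-fit by wide Gaussians
    (``background="gaussians"``).  Non-convergent or vanishing peaks are
    flagged rather than raised, so batch processing continues; parameters
    are reported from the best iterate.
    """
    x = trace.coordinate
    y = trace.intensity.astype(np.float64)
    if background == "hull":
        y = y - convex_hull_baseline(trace)
    elif background != "gaussians":
        raise ValueError("background must be 'hull' or 'gaussians'")

    span = x[-1] - x[0]
    scale = float(np.max(np.abs(y))) if np.any(y) else 0.0
    model = None
    for i, c0 in enumerate(initial_centers):
        g = lmfit.models.GaussianModel(prefix=f"p{i}_")
        model = g if model is None else model + g
    if background == "gaussians":
        for i in range(n_background_gaussians):
            g = lmfit.models.GaussianModel(prefix=f"bg{i}_")
            model = g if model is None else model + g

    params = model.make_params()
    for i, c0 in enumerate(initial_centers):
        j = int(np.argmin(np.abs(x - c0)))
        amp0 = max(y[j], scale * 0.05, 1e-12)
        sig0 = max(span / (10.0 * max(len(list(initial_centers)), 1)), 1.0)
        params[f"p{i}_center"].set(value=c0, min=c0 - span / 4, max=c0 + span / 4)
        params[f"p{i}_sigma"].set(value=sig0, min=0.2, max=span)
        params[f"p{i}_amplitude"].set(value=amp0 * sig0 * math.sqrt(2 * math.pi), min=0.0)
    if background == "gaussians":
        for i in range(n_background_gaussians):
            params[f"bg{i}_center"].set(value=x[0] + span * (i + 1) / (n_background_gaussians + 1))
            params[f"bg{i}_sigma"].set(value=span / 2, min=span / 8, max=4 * span)
            params[f"bg{i}_amplitude"].set(value=max(scale, 1e-12) * span / 4, min=0.0)

    result = model.fit(y, params, x=x)
    out = []
    for i, _ in enumerate(initial_centers):
        area = float(result.params[f"p{i}_amplitude"].value)
        sigma = float(result.params[f"p{i}_sigma"].value)
        center = float(result.params[f"p{i}_center"].value)
        height = area / (sigma * math.sqrt(2 * math.pi)) if sigma > 0 else 0.0
        flag = (not result.success) or height <= max(scale, 1.0) * 1e-9
        out.append(GaussPeakFit(center, area, sigma, flag))
    return out


def centroid_top_half(trace: Trace, window: tuple[float, float]) -> PeakMeasurement:
    """Measure a peak by the centroid of its top half (Huxley-style).

    Within ``window`` the peak height is the maximum; the half-height level
    splits the peak, and the centroid is the level-referenced first moment
    over the samples strictly above it:
    ``sum(x * (I - level)) / sum(I - level)``.  The FWHM comes from
    linear-interpolated half-height crossings and the triangular area is
    ``height * FWHM``.  A flat or empty window yields a flagged measurement.
    """
    lo, hi = window
    sel = (trace.coordinate >= lo) & (trace.coordinate <= hi)
    x = trace.coordinate[sel]
    inten = trace.intensity[sel]
    if x.size < 3 or np.max(inten) <= 0:
        return PeakMeasurement(np.nan, 0.0, np.nan, np.nan, flagged=True)

    ipk = int(np.argmax(inten))
    height = float(inten[ipk])
    level = height / 2.0
    above = inten > level
    weights = inten[above] - level
    if weights.sum() <= 0:
        return PeakMeasurement(np.nan, height, np.nan, np.nan, flagged=True)
    centroid = float(np.sum(x[above] * weights) / np.sum(weights))

    flagged = False

    def _crossing(idx_range, direction):
        prev = ipk
        for j in idx_range:
            if inten[j] <= level:
                x0, x1 = x[j], x[prev]
                y0, y1 = inten[j], inten[prev]
                if y1 == y0:
                    return x0
                return x0 + (level - y0) * (x1 - x0) / (y1 - y0)
            prev = j
        return None

    left = _crossing(range(ipk - 1, -1, -1), -1)
    right = _crossing(range(ipk + 1, x.size), +1)
    if left is None or right is None:
        flagged = True
        left = x[0] if left is None else left
        right = x[-1] if right is None else right
    halfwidth = float(right - left)
    return PeakMeasurement(
        centroid=centroid,
        height=height,
        halfwidth=halfwidth,
        triangular_area=height * halfwidth,
        flagged=flagged,
    )


def measure_distance(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Euclidean pixel distance between two image points."""
    return math.hypot(p2[0] - p1[0], p2[1] - p1[1])
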