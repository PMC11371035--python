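"""Estimation and subtraction of the smooth diffuse 2-D background.

Muscle patterns sit on a large diffuse background (incoherent scattering
from membranes, myosin heads, connective tissue).  No single estimator works
everywhere, so five are provided — circularly symmetric, iterative Gaussian
smoothing, iterative smoothed boxcar, roving-window order statistic, and
morphological white top-hat — plus a radial blend so different estimators
can serve the low- and high-radius halves of the pattern.

All estimators are equivariant under adding a constant, and all but the
circular one are clamped to lie at or below the image pointwise, so the
estimate is always an under-estimate of the local surface.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening

__all__ = [
    "bg_circular",
    "bg_iterative_smooth",
    "bg_roving_window",
    "bg_tophat",
    "merge_backgrounds",
    "subtract_background",
    "estimate_background",
]


def _radius_map(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    cx, cy = center
    yy, xx = np.indices(shape)
    return np.hypot(xx - cx, yy - cy)


def bg_circular(
    image: np.ndarray,
    center: tuple[float, float],
    bin_width: float = 2.0,
    percentile: float = 50.0,
    smooth_bins: int = 5,
    min_valid: float | None = None,
) -> np.ndarray:
    """Circularly symmetric background from per-annulus percentiles.

    Pixels are grouped into annuli of ``bin_width`` pixels about ``center``;
    the requested low ``percentile`` of each annulus forms a radial profile,
    smoothed by a moving average of ``smooth_bins`` bins and back-projected
    circularly.  Empty annuli (all pixels masked via ``min_valid``) are
    interpolated from their neighbours.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    r = _radius_map(img.shape, center)
    rbin = (r / bin_width).astype(np.intp)
    nbins = int(rbin.max()) + 1

    valid = np.isfinite(img)
    if min_valid is not None:
        valid &= img >= min_valid
    profile = np.full(nbins, np.nan)
    flat_bins = rbin[valid].ravel()
    flat_vals = img[valid].ravel()
    flat_r = r[valid].ravel()
    order = np.argsort(flat_bins, kind="stable")
    flat_bins = flat_bins[order]
    flat_vals = flat_vals[order]
    flat_r = flat_r[order]
    edges = np.searchsorted(flat_bins, np.arange(nbins + 1))
    # abscissa: for a radially decreasing surface the value percentile p of
    # an annulus occurs at the radius percentile 100-p, so pairing the two
    # removes the within-bin discretization bias of a fixed bin center
    centers = (np.arange(nbins) + 0.5) * bin_width
    for b in range(nbins):
        lo, hi = edges[b], edges[b + 1]
        if hi > lo:
            profile[b] = np.percentile(flat_vals[lo:hi], percentile)
            centers[b] = np.percentile(flat_r[lo:hi], 100.0 - percentile)

    # fill empty annuli by interpolation from populated neighbours
    bad = np.isnan(profile)
    if bad.all():
        raise ValueError("no valid pixels for circular background")
    if bad.any():
        idx = np.arange(nbins)
        profile[bad] = np.interp(idx[bad], idx[~bad], profile[~bad])

    if smooth_bins > 1:
        k = int(smooth_bins)
        pad = np.pad(profile, k // 2, mode="edge")
        profile = np.convolve(pad, np.ones(k) / k, mode="valid")[:nbins]

    # anchor both ends so the extreme radii (beam center, image corners)
    # interpolate instead of clamping at the last percentile node
    lo_last, hi_last = edges[-2], edges[-1]
    r_nodes = np.concatenate([[flat_r.min() - 1e-9], centers, [flat_r.max() + 1e-9]])
    v_nodes = np.concatenate([[profile[0]], profile, [profile[-1]]])
    if hi_last > lo_last:
        v_nodes[-1] = flat_vals[lo_last:hi_last].min()
    order2 = np.argsort(r_nodes, kind="stable")
    return np.interp(r, r_nodes[order2], v_nodes[order2]).astype(np.float32)


def bg_iterative_smooth(
    image: np.ndarray,
    kernel: str = "gaussian",
    width: float = 10.0,
    iterations: int = 20,
) -> np.ndarray:
    """Iterative smooth-and-clamp background (Ivanova-Makowski / CCP13 style).

    Starting from ``B = I``, iterate ``B <- min(smooth(B), I)`` where
    ``smooth`` is a Gaussian blur of sigma ``width`` or a ``width x width``
    boxcar mean.  The clamp keeps ``B <= I`` pointwise at every step and
    makes ``B`` monotone non-increasing across iterations; peaks narrower
    than the kernel are progressively eroded out of the estimate.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    if kernel == "gaussian":
        smooth = lambda a: ndimage.gaussian_filter(a, sigma=width, mode="nearest")
    elif kernel == "boxcar":
        smooth = lambda a: ndimage.uniform_filter(a, size=int(width), mode="nearest")
    else:
        raise ValueError(f"kernel must be 'gaussian' or 'boxcar', got {kernel!r}")
    bg = img.copy()
    for _ in range(int(iterations)):
        bg = np.minimum(smooth(bg), img)
    return bg.astype(np.float32)


def bg_roving_window(
    image: np.ndarray,
    win_w: int = 21,
    win_h: int = 21,
    percentile: float = 10.0,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Roving-window background: local low order statistic, lightly smoothed.

    Each pixel takes the given low ``percentile`` of the centered
    ``win_w x win_h`` window (edge-clipped), followed by a small Gaussian
    smooth and a final clamp to the image so the estimate never exceeds the
    data.
    """
    for name, v in (("win_w", win_w), ("win_h", win_h)):
        if v < 3 or v % 2 == 0:
            raise ValueError(f"{name} must be odd and >= 3")
    img = np.asarray(image, dtype=np.float64)
    bg = ndimage.percentile_filter(
        img, percentile, size=(int(win_h), int(win_w)), mode="nearest"
    )
    if smooth_sigma > 0:
        bg = ndimage.gaussian_filter(bg, sigma=smooth_sigma, mode="nearest")
    return np.minimum(bg, img).astype(np.float32)


def bg_tophat(image: np.ndarray, selem_radius: int = 15) -> np.ndarray:
    """White top-hat background: the grayscale opening with a disc.

    The opening removes features narrower than the disc while following the
    broad surface; anti-extensivity guarantees ``opening <= image``
    pointwise.  The white top-hat (image minus opening) is then the
    background-free signal.
    """
    if selem_radius < 1:
        raise ValueError("selem_radius must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    return opening(img, footprint=disk(int(selem_radius))).astype(np.float32)


def merge_backgrounds(
    bg_inner: np.ndarray,
    bg_outer: np.ndarray,
    center: tuple[float, float],
    merge_radius: float,
    transition_width: float,
) -> np.ndarray:
    """Blend two background estimates radially with a logistic weight.

    ``B(r) = w(r) * bg_inner + (1 - w(r)) * bg_outer`` with
    ``w(r) = 1 / (1 + exp((r - merge_radius) / transition_width))`` — the
    inner estimate dominates at low radius, the outer at high radius, and
    the weight is exactly 0.5 at ``merge_radius``.
    """
    if merge_radius <= 0 or transition_width <= 0:
        raise ValueError("merge_radius and transition_width must be > 0")
    a = np.asarray(bg_inner, dtype=np.float64)
    b = np.asarray(bg_outer, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("background shapes differ")
    r = _radius_map(a.shape, center)
    w = 1.0 / (1.0 + np.exp((r - merge_radius) / transition_width))
    return (w * a + (1.0 - w) * b).astype(np.float32)


def subtract_background(
    image: np.ndarray,
    background: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Subtract a background estimate and report its total intensity.

    Negatives are preserved (over-subtraction is diagnostic, not an error).
    ``background_total`` is the sum of the background over unmasked pixels;
    it is the per-pattern scaling quantity written to the results table.
    """
    img = np.asarray(image, dtype=np.float32)
    bg = np.asarray(background, dtype=np.float32)
    if img.shape != bg.shape:
        raise ValueError("image and background shapes differ")
    sub = (img - bg).astype(np.float32)
    if mask is not None:
        total = float(np.sum(bg[np.asarray(mask) != 0], dtype=np.float64))
    else:
        total = float(np.sum(bg, dtype=np.float64))
    return sub, total


_ALGORITHMS = {
    "circular": bg_circular,
    "gauss_smooth": lambda img, center, **p: bg_iterative_smooth(img, "gaussian", **p),
    "boxcar_smooth": lambda img, center, **p: bg_iterative_smooth(img, "boxcar", **p),
    "roving_window": lambda img, center, **p: bg_roving_window(img, **p),
    "tophat": lambda img, center, **p: bg_tophat(img, **p),
}


def estimate_background(
    image: np.ndarray,
    center: tuple[float, float],
    method: str,
    params: dict | None = None,
    method2: str | None = None,
    params2: dict | None = None,
    merge_radius: float | None = None,
    transition_width: float | None = None,
) -> np.ndarray:
    """Dispatch a background estimate by name, with optional radial merging.

    ``method`` serves the whole image; when ``method2`` is given, ``method``
    serves low radii and ``method2`` high radii, blended at ``merge_radius``
    over ``transition_width`` (both required, in pixels).
    """
    if method not in _ALGORITHMS:
        raise ValueError(f"unknown background algorithm: {method!r}")
    bg = _ALGORITHMS[method](image, center, **(params or {}))
    if method2 is not None:
        if method2 not in _ALGORITHMS:
            raise ValueError(f"unknown background algorithm: {method2!r}")
        if merge_radius is None or transition_width is None:
            raise ValueError("merging requires merge_radius and transition_width")
        bg2 = _ALGORITHMS[method2](image, center, **(params2 or {}))
        bg = merge_backgrounds(bg, bg2, center, merge_radius, transition_width)
    return bg
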