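"""Equatorial analysis of hexagonally packed filament lattices.

The equator of a muscle diffraction pattern carries reflections from the
hexagonal myofilament lattice at radial offsets ``S10 * Z_hk`` with
``Z_hk = sqrt(h^2 + hk + k^2)``.  This module projects the equator into a
1-D trace, removes the diffuse background with a convex hull, and fits a
bilateral sum of Gaussian or Voigt peaks whose positions are constrained to
the lattice and whose widths follow a para-crystalline disorder model
``w(h,k) = sigma_s + sigma_d * Z^2`` (constant lattice-spacing-spread term
plus liquid-like second-kind disorder growing with the square of the
reflection order).  Derived physiology numbers are the d10 spacing (nm,
when calibrated) and the I11/I10 intensity ratio.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import lmfit
from scipy import signal as sps
from scipy.special import voigt_profile

from .geometry import Calibration, PatternFrame, find_center, find_rotation, pixel_to_d, rectify
from .exceptions import OrientationUndeterminedError
from .trace1d import Box, Trace, convex_hull_baseline, project_box

__all__ = [
    "HexLatticeFit",
    "EquatorSettings",
    "hex_offsets",
    "paracrystal_width",
    "analyze_equator",
    "refit_with_overrides",
]

DEFAULT_HK_LIST = ((1, 0), (1, 1), (2, 0), (2, 1), (3, 0))


def _z(h: int, k: int) -> float:
    return math.sqrt(h * h + h * k + k * k)


def hex_offsets(S10: float, hk_list) -> np.ndarray:
    """Radial peak offsets ``S10 * sqrt(h^2 + hk + k^2)`` in pixels.

    Strictly increasing in the lattice index ``Z``; (0,0) is the direct
    beam, not a reflection, and is rejected.
    """
    if S10 <= 0:
        raise ValueError("S10 must be > 0")
    out = []
    for h, k in hk_list:
        if h == 0 and k == 0:
            raise ValueError("(0,0) is not a reflection")
        out.append(S10 * _z(h, k))
    return np.asarray(out)


def paracrystal_width(sigma_s: float, sigma_d: float, hk) -> float:
    """Para-crystalline peak width ``sigma_s + sigma_d * Z^2`` in pixels.

    ``sigma_s`` models the spread of lattice spacings across the specimen
    (order-independent), ``sigma_d`` the liquid-like disorder of the second
    kind whose broadening grows with the square of the reflection order.
    """
    if sigma_s < 0 or sigma_d < 0:
        raise ValueError("width parameters must be >= 0")
    h, k = hk
    z = _z(h, k)
    return sigma_s + sigma_d * z * z


@dataclasses.dataclass
class EquatorSettings:
    """Tunable parameters of the equator pipeline."""

    hk_list: tuple = DEFAULT_HK_LIST
    model: str = "gaussian"  # or "voigt"
    box_height: int | None = None  # px; None -> estimated from axial widths
    box_height_factor: float = 4.0  # half-height = factor * axial sigma
    min_offset: float = 10.0  # px; ignore peaks closer to the centerline
    reject_threshold: float = 0.10  # normalized residual RMS above -> flagged
    orientation_method: str = "azimuthal"
    extra_peaks: tuple = ()  # initial centers (px offsets) of non-indexing peaks
    sentinel_threshold: float | None = None


@dataclasses.dataclass
class HexLatticeFit:
    """Fitted equatorial model and its derived physiology parameters."""

    S10: float
    d10: float | None
    centerline: float
    areas: dict  # (h,k) -> fitted area
    widths: dict  # (h,k) -> model width (px)
    extra_peaks: list  # (center, area, sigma)
    I11_over_I10: float | None
    sigma_s: float
    sigma_d: float
    model: str
    fit_error: float
    flagged: bool
    trace: Trace | None = None
    residual_trace: np.ndarray | None = None
    settings: EquatorSettings | None = None
    calibration: Calibration | None = None
    message: str = ""

    def as_row(self) -> dict:
        """Flatten to one CSV row of scalars."""
        row = {
            "S10_px": self.S10,
            "d10_nm": self.d10,
            "centerline_px": self.centerline,
            "sigma_s_px": self.sigma_s,
            "sigma_d_px": self.sigma_d,
            "model": self.model,
            "fit_error": self.fit_error,
            "flagged": self.flagged,
        }
        for (h, k), a in self.areas.items():
            row[f"I{h}{k}"] = a
        row["I11_over_I10"] = self.I11_over_I10
        return row


def _profile_matrix(x, centers, widths, model, gamma_frac):
    """Stack of area-normalized bilateral peak profiles, one row per (h,k)."""
    rows = []
    for c, wdt in zip(centers, widths):
        if model == "voigt":
            g = gamma_frac * wdt
            rows.append(voigt_profile(x - c, wdt, g) + voigt_profile(x + c, wdt, g))
        else:
            rows.append(
                np.exp(-0.5 * ((x - c) / wdt) ** 2) / (wdt * math.sqrt(2 * math.pi))
                + np.exp(-0.5 * ((x + c) / wdt) ** 2) / (wdt * math.sqrt(2 * math.pi))
            )
    return np.array(rows)


def _model_eval(params, x, hk_list, model, n_extra):
    c = params["centerline"].value
    s10 = params["S10"].value
    ss = params["sigma_s"].value
    sd = params["sigma_d"].value
    gf = params["gamma_frac"].value if "gamma_frac" in params else 0.0
    xs = x - c
    zs = [_z(h, k) for h, k in hk_list]
    centers = [s10 * z for z in zs]
    widths = [ss + sd * z * z for z in zs]
    mat = _profile_matrix(xs, centers, widths, model, gf)
    areas = np.array([params[f"A_{h}{k}"].value for h, k in hk_list])
    y = areas @ mat
    for i in range(n_extra):
        ec = params[f"ex{i}_center"].value
        ea = params[f"ex{i}_area"].value
        es = params[f"ex{i}_sigma"].value
        y = y + ea * (
            np.exp(-0.5 * ((xs - ec) / es) ** 2) / (es * math.sqrt(2 * math.pi))
            + np.exp(-0.5 * ((xs + ec) / es) ** 2) / (es * math.sqrt(2 * math.pi))
        )
    return y


def evaluate_model(fit: HexLatticeFit, x: np.ndarray) -> np.ndarray:
    """Forward-evaluate a fitted (or hand-built) bilateral lattice model."""
    hk_list = tuple(fit.areas.keys())
    base = fit.settings or EquatorSettings(model=fit.model)
    settings = dataclasses.replace(base, hk_list=hk_list, model=fit.model)
    params = _build_params(
        settings,
        S10=fit.S10,
        centerline=fit.centerline,
        sigma_s=fit.sigma_s,
        sigma_d=fit.sigma_d,
        areas=fit.areas,
        extras=fit.extra_peaks,
        x_max=float(np.max(np.abs(x))) if len(x) else None,
    )
    return _model_eval(params, x, hk_list, fit.model, len(fit.extra_peaks))


def _build_params(
    settings: EquatorSettings,
    S10: float,
    centerline: float,
    sigma_s: float,
    sigma_d: float,
    areas: dict,
    extras=(),
    x_max: float | None = None,
) -> lmfit.Parameters:
    p = lmfit.Parameters()
    hi = x_max if x_max is not None else S10 * 10
    p.add("centerline", value=centerline, min=centerline - 20, max=centerline + 20)
    p.add("S10", value=S10, min=max(3.0, 0.5 * S10), max=min(2.0 * S10, hi))
    p.add("sigma_s", value=sigma_s, min=0.3, max=30.0)
    p.add("sigma_d", value=sigma_d, min=0.0, max=5.0)
    if settings.model == "voigt":
        p.add("gamma_frac", value=0.05, min=0.0, max=1.0)
    for (h, k) in settings.hk_list:
        p.add(f"A_{h}{k}", value=float(areas.get((h, k), 0.0)), min=0.0)
    for i, ex in enumerate(extras):
        ec, ea, es = ex
        p.add(f"ex{i}_center", value=ec, min=max(1.0, 0.7 * ec), max=1.3 * ec)
        p.add(f"ex{i}_area", value=ea, min=0.0)
        p.add(f"ex{i}_sigma", value=es, min=0.3, max=30.0)
    return p


def _estimate_box_height(img, cx, cy, factor):
    """First-pass axial extent of the strongest off-center equatorial peak."""
    h, w = img.shape
    band = img[max(0, int(cy) - 2) : int(cy) + 3, :]
    prof = band.mean(axis=0)
    cols = np.arange(w)
    off = np.abs(cols - cx)
    prof = np.where(off > 5, prof, -np.inf)
    jpk = int(np.argmax(prof))
    col = img[:, jpk].astype(np.float64)
    col = np.clip(col - np.median(col), 0, None)
    if col.sum() <= 0:
        return 20
    rows = np.arange(h)
    mu = np.sum(rows * col) / col.sum()
    sig = math.sqrt(max(np.sum((rows - mu) ** 2 * col) / col.sum(), 1.0))
    return int(np.clip(2 * factor * min(sig, h / 6), 5, h - 1))


def _initial_s10(x, y, min_offset):
    """Guess S10 by scoring candidate lattices against detected peaks."""
    height = 0.05 * np.max(y) if np.max(y) > 0 else 0.0
    idx, props = sps.find_peaks(y, height=height, distance=3)
    offs = np.abs(x[idx])
    keep = offs > min_offset
    idx, offs = idx[keep], offs[keep]
    if idx.size == 0:
        return None
    heights = y[idx]
    order = np.argsort(heights)[::-1][:6]
    cand_offs = offs[order]
    zs = np.array([_z(h, k) for h, k in DEFAULT_HK_LIST])
    best, best_score = None, np.inf
    for o in cand_offs:
        for z0 in (1.0, math.sqrt(3.0)):
            s10 = o / z0
            if s10 <= min_offset / 2:
                continue
            pred = s10 * zs
            # mean fractional mismatch of detected peaks to nearest predicted
            score = np.mean(
                [min(abs(oo - pred).min() / s10, 0.5) for oo in cand_offs]
            )
            if score < best_score:
                best, best_score = s10, score
    return best


def analyze_equator(
    image: np.ndarray,
    cal: Calibration | None = None,
    settings: EquatorSettings | None = None,
    frame: PatternFrame | None = None,
) -> HexLatticeFit:
    """Run the full equatorial pipeline on one pattern.

    Steps: detect (or accept) the pattern frame and rectify; size an
    integration box from the axial extent of the strongest reflection;
    project onto the equator; remove the diffuse background with a convex
    hull on each side of the centerline; fit the bilateral
    lattice-constrained peak model; derive d10 (when calibrated) and
    I11/I10.  Failures return a flagged result with diagnostics so batch
    runs continue.
    """
    settings = settings or EquatorSettings()
    img = np.asarray(image, dtype=np.float64)

    def _failure(msg: str) -> HexLatticeFit:
        return HexLatticeFit(
            S10=np.nan, d10=None, centerline=np.nan, areas={}, widths={},
            extra_peaks=[], I11_over_I10=None, sigma_s=np.nan, sigma_d=np.nan,
            model=settings.model, fit_error=np.nan, flagged=True,
            settings=settings, calibration=cal, message=msg,
        )

    if frame is None:
        center = find_center(img)
        try:
            rot = find_rotation(img, center, method=settings.orientation_method)
        except OrientationUndeterminedError:
            rot = 0.0
        frame = PatternFrame(center, rot)
    if frame.rotation != 0.0:
        fill = settings.sentinel_threshold - 1 if settings.sentinel_threshold is not None else -1.0
        img, frame = rectify(img, frame, fill_value=fill)
        img = np.asarray(img, dtype=np.float64)
    cx, cy = frame.center

    box_h = settings.box_height or _estimate_box_height(
        img, cx, cy, settings.box_height_factor
    )
    length = img.shape[1]
    box = Box("equator_axial", anchor=(cx, cy), length=length, width=box_h)
    trace = project_box(img, box, sentinel_threshold=settings.sentinel_threshold)
    x, y = trace.coordinate, trace.intensity

    # hull-subtract each side outward from the centerline
    resid = y.copy()
    for sel in (x <= 0, x >= 0):
        if sel.sum() >= 3:
            side = Trace(x[sel], y[sel])
            resid[sel] = y[sel] - convex_hull_baseline(side)
    resid = np.clip(resid, 0.0, None)

    s10_0 = _initial_s10(x, resid, settings.min_offset)
    if s10_0 is None:
        return _failure("no off-center equatorial peaks detected")

    zs = {hk: _z(*hk) for hk in settings.hk_list}
    areas0 = {}
    for hk, z in zs.items():
        target = s10_0 * z
        j = int(np.argmin(np.abs(np.abs(x) - target)))
        w0 = 2.0 + 0.3 * z * z
        areas0[hk] = max(resid[j] * w0 * math.sqrt(2 * math.pi) / 2.0, 0.0)
    extras0 = [(ec, np.max(resid) * 2.0, 3.0) for ec in settings.extra_peaks]

    params = _build_params(
        settings, S10=s10_0, centerline=0.0, sigma_s=2.0, sigma_d=0.1,
        areas=areas0, extras=extras0, x_max=float(np.max(np.abs(x))),
    )
    n_extra = len(extras0)

    def residual(p):
        return _model_eval(p, x, settings.hk_list, settings.model, n_extra) - resid

    try:
        result = lmfit.minimize(residual, params, method="leastsq")
        ok = result.success
        params = result.params
    except Exception as exc:  # keep the batch alive on optimizer blowups
        return _failure(f"optimizer failure: {exc}")

    yhat = _model_eval(params, x, settings.hk_list, settings.model, n_extra)
    rms_resid = float(np.sqrt(np.mean((yhat - resid) ** 2)))
    rms_trace = float(np.sqrt(np.mean(resid**2)))
    fit_error = rms_resid / rms_trace if rms_trace > 0 else np.nan

    s10 = float(params["S10"].value)
    ss = float(params["sigma_s"].value)
    sd = float(params["sigma_d"].value)
    areas = {hk: float(params[f"A_{hk[0]}{hk[1]}"].value) for hk in settings.hk_list}
    widths = {hk: ss + sd * zs[hk] ** 2 for hk in settings.hk_list}
    extras = [
        (
            float(params[f"ex{i}_center"].value),
            float(params[f"ex{i}_area"].value),
            float(params[f"ex{i}_sigma"].value),
        )
        for i in range(n_extra)
    ]
    a10 = areas.get((1, 0))
    a11 = areas.get((1, 1))
    ratio = (a11 / a10) if (a10 and a11 is not None and a10 > 0) else None
    d10 = float(pixel_to_d(s10, cal)) if (cal is not None and cal.calibrated) else None
    flagged = (not ok) or not np.isfinite(fit_error) or fit_error > settings.reject_threshold

    return HexLatticeFit(
        S10=s10, d10=d10, centerline=float(params["centerline"].value),
        areas=areas, widths=widths, extra_peaks=extras, I11_over_I10=ratio,
        sigma_s=ss, sigma_d=sd, model=settings.model, fit_error=fit_error,
        flagged=flagged, trace=Trace(x, resid), residual_trace=yhat - resid,
        settings=settings, calibration=cal,
        message="" if not flagged else "fit rejected or optimizer failed",
    )


def refit_with_overrides(previous: HexLatticeFit, overrides: dict) -> HexLatticeFit:
    """Re-run a fit from manually adjusted initial values.

    ``overrides`` maps parameter names (``S10``, ``centerline``, ``sigma_s``,
    ``sigma_d``, ``A_hk`` like ``A_10``, or ``extra_peaks`` — a list of
    ``(center, area, sigma)`` triples to add) to new initial values.  An
    unknown name raises; an empty dict reproduces the previous fit.
    """
    if previous.trace is None or previous.settings is None:
        raise ValueError("previous fit carries no trace to refit")
    settings = previous.settings
    x, resid = previous.trace.coordinate, previous.trace.intensity

    s10_0 = previous.S10 if np.isfinite(previous.S10) else None
    areas0 = dict(previous.areas)
    extras0 = list(previous.extra_peaks)
    ss0 = previous.sigma_s if np.isfinite(previous.sigma_s) else 2.0
    sd0 = previous.sigma_d if np.isfinite(previous.sigma_d) else 0.1
    c0 = 0.0

    known = {"S10", "centerline", "sigma_s", "sigma_d", "extra_peaks"}
    known |= {f"A_{h}{k}" for h, k in settings.hk_list}
    for name, value in overrides.items():
        if name not in known:
            raise ValueError(f"unknown override parameter: {name!r}")
        if name == "S10":
            s10_0 = float(value)
        elif name == "centerline":
            c0 = float(value)
        elif name == "sigma_s":
            ss0 = float(value)
        elif name == "sigma_d":
            sd0 = float(value)
        elif name == "extra_peaks":
            extras0 = extras0 + [tuple(v) for v in value]
        else:
            h, k = int(name[2]), int(name[3])
            areas0[(h, k)] = float(value)
    if s10_0 is None:
        s10_0 = _initial_s10(x, resid, settings.min_offset)
        if s10_0 is None:
            raise ValueError("cannot refit: no S10 available")

    params = _build_params(
        settings, S10=s10_0, centerline=c0, sigma_s=ss0, sigma_d=sd0,
        areas=areas0, extras=extras0, x_max=float(np.max(np.abs(x))),
    )
    n_extra = len(extras0)

    def residual(p):
        return _model_eval(p, x, settings.hk_list, settings.model, n_extra) - resid

    result = lmfit.minimize(residual, params, method="leastsq")
    params = result.params
    yhat = _model_eval(params, x, settings.hk_list, settings.model, n_extra)
    rms_resid = float(np.sqrt(np.mean((yhat - resid) ** 2)))
    rms_trace = float(np.sqrt(np.mean(resid**2)))
    fit_error = rms_resid / rms_trace if rms_trace > 0 else np.nan
    zs = {hk: _z(*hk) for hk in settings.hk_list}
    s10 = float(params["S10"].value)
    ss = float(params["sigma_s"].value)
    sd = float(params["sigma_d"].value)
    areas = {hk: float(params[f"A_{hk[0]}{hk[1]}"].value) for hk in settings.hk_list}
    extras = [
        (
            float(params[f"ex{i}_center"].value),
            float(params[f"ex{i}_area"].value),
            float(params[f"ex{i}_sigma"].value),
        )
        for i in range(n_extra)
    ]
    a10, a11 = areas.get((1, 0)), areas.get((1, 1))
    ratio = (a11 / a10) if (a10 and a11 is not None and a10 > 0) else None
    cal = previous.calibration
    d10 = float(pixel_to_d(s10, cal)) if (cal is not None and cal.calibrated) else None
    flagged = (not result.success) or not np.isfinite(fit_error) or fit_error > settings.reject_threshold
    return HexLatticeFit(
        S10=s10, d10=d10, centerline=float(params["centerline"].value),
        areas=areas, widths={hk: ss + sd * zs[hk] ** 2 for hk in settings.hk_list},
        extra_peaks=extras, I11_over_I10=ratio, sigma_s=ss, sigma_d=sd,
        model=settings.model, fit_error=fit_error, flagged=flagged,
        trace=previous.trace, residual_trace=yhat - resid,
        settings=settings, calibration=cal,
    )
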