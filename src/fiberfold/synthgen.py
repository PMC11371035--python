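"""Synthetic fiber-diffraction patterns with exact ground truth.

Every recovery test in the suite runs against patterns built here: bilateral
equatorial reflections on a hexagonal lattice (anisotropic 2-D Gaussians,
para-crystal-widened radially, narrow axially), meridional reflections,
smooth circular diffuse background, Poisson counting noise, detector gap
stripes, and arbitrary center/rotation offsets.  The spec that built a
pattern is returned alongside it, so the generator doubles as the oracle.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

__all__ = ["SyntheticSpec", "generate_pattern", "generate_sequence", "generate_ring"]


@dataclasses.dataclass
class SyntheticSpec:
    """Recipe for one synthetic pattern.

    ``eq_peaks`` lists ``((h, k), area, extra_width)`` — each side of a
    bilateral pair carries total 2-D mass ``area`` so the equatorial
    projection reproduces the area exactly; radial width is
    ``sigma_s + sigma_d * Z^2 + extra_width``.  ``mer_peaks`` lists
    ``(axial_position, area, width)``.  ``background`` lists circular
    ``("exp"|"gauss", amplitude, length_scale)`` terms.  ``gaps`` lists
    ``("h"|"v", start, width)`` stripes painted to ``gap_value``.
    """

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] | None = None  # default: exact image middle
    rotation: float = 0.0
    S10: float = 50.0
    eq_peaks: tuple = (((1, 0), 2.0e5, 0.0), ((1, 1), 1.2e5, 0.0), ((2, 0), 3.0e4, 0.0))
    sigma_s: float = 2.0
    sigma_d: float = 0.3
    axial_sigma: float = 4.0
    mer_peaks: tuple = ()
    background: tuple = (("exp", 200.0, 60.0),)
    noise: str = "none"  # or "poisson"
    gaps: tuple = ()
    gap_value: float = -1.0
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        h, w = self.shape
        if self.center is not None:
            return self.center
        return ((w - 1) / 2.0, (h - 1) / 2.0)


def _gauss2d(u, v, u0, su, sv, mass):
    norm = mass / (2.0 * math.pi * su * sv)
    return norm * np.exp(-0.5 * (((u - u0) / su) ** 2 + (v / sv) ** 2))


def generate_pattern(spec: SyntheticSpec) -> tuple[np.ndarray, dict]:
    """Render a pattern and return ``(image, ground_truth)``.

    ``ground_truth`` holds the spec, the noise-free image (``clean``) and
    convenience entries (center, rotation, S10, per-peak areas/widths).
    Features are evaluated analytically in the rotated frame, so rotation
    introduces no interpolation error.
    """
    h, w = spec.shape
    cx, cy = spec.resolved_center()
    yy, xx = np.indices((h, w), dtype=np.float64)
    dx, dy = xx - cx, yy - cy
    theta = math.radians(spec.rotation)
    ca, sa = math.cos(theta), math.sin(theta)
    u = dx * ca + dy * sa  # along the equator
    v = -dx * sa + dy * ca  # along the meridian

    img = np.zeros((h, w), dtype=np.float64)
    r = np.hypot(u, v)
    for kind, amp, scale in spec.background:
        if kind == "exp":
            img += amp * np.exp(-r / scale)
        elif kind == "gauss":
            img += amp * np.exp(-0.5 * (r / scale) ** 2)
        else:
            raise ValueError(f"unknown background term: {kind!r}")

    widths = {}
    for (hk, area, extra) in spec.eq_peaks:
        hh, kk = hk
        z = math.sqrt(hh * hh + hh * kk + kk * kk)
        off = spec.S10 * z
        su = spec.sigma_s + spec.sigma_d * z * z + extra
        widths[hk] = su
        reach = math.hypot(max(cx, w - 1 - cx), max(cy, h - 1 - cy))
        if off - 3 * su > reach:
            import warnings

            warnings.warn(f"equatorial peak {hk} lies outside the image; clipped")
        img += _gauss2d(u, v, +off, su, spec.axial_sigma, area)
        img += _gauss2d(u, v, -off, su, spec.axial_sigma, area)
    for pos, area, width in spec.mer_peaks:
        img += _gauss2d(v, u, +pos, width, spec.axial_sigma, area)
        img += _gauss2d(v, u, -pos, width, spec.axial_sigma, area)

    clean = img.astype(np.float32)
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        img = rng.poisson(np.clip(img, 0, None)).astype(np.float64)
    elif spec.noise != "none":
        raise ValueError(f"unknown noise model: {spec.noise!r}")

    for axis, start, width in spec.gaps:
        if axis == "h":
            img[int(start) : int(start) + int(width), :] = spec.gap_value
        elif axis == "v":
            img[:, int(start) : int(start) + int(width)] = spec.gap_value
        else:
            raise ValueError(f"gap axis must be 'h' or 'v', got {axis!r}")

    truth = {
        "spec": spec,
        "clean": clean,
        "center": (cx, cy),
        "rotation": spec.rotation,
        "S10": spec.S10,
        "areas": {hk: area for hk, area, _ in spec.eq_peaks},
        "widths": widths,
        "I11_over_I10": _ratio(spec),
    }
    return img.astype(np.float32), truth


def _ratio(spec: SyntheticSpec):
    areas = {hk: a for hk, a, _ in spec.eq_peaks}
    if (1, 0) in areas and (1, 1) in areas and areas[(1, 0)] > 0:
        return areas[(1, 1)] / areas[(1, 0)]
    return None


def generate_ring(
    shape=(1024, 1024),
    center=(512.0, 512.0),
    radius=200.0,
    ring_sigma=2.0,
    amplitude=1000.0,
) -> np.ndarray:
    """A single powder ring (Gaussian radial cross-section) for calibration."""
    h, w = shape
    yy, xx = np.indices((h, w), dtype=np.float64)
    r = np.hypot(xx - center[0], yy - center[1])
    return (amplitude * np.exp(-0.5 * ((r - radius) / ring_sigma) ** 2)).astype(
        np.float32
    )


def generate_sequence(
    spec: SyntheticSpec,
    n_frames: int,
    out_dir,
    drift: dict | None = None,
    basename: str = "frame",
    hdf5: bool = False,
) -> list[Path]:
    """Write a sequence of drifting frames as float32 TIFFs (+ optional HDF5).

    ``drift`` maps parameter names (``S10``, ``rotation``, ``area_scale``)
    to per-frame increments; frame ``i`` uses the base value plus
    ``i * delta`` (``area_scale`` multiplies all peak areas by
    ``1 + i * delta``).  Poisson frames use ``spec.seed + i``.  Ground truth
    per frame goes to ``<basename>_truth.csv``; with ``hdf5=True`` the whole
    stack is also written to ``<basename>.h5`` under dataset ``"data"``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    drift = drift or {}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths, rows, stack = [], [], []
    for i in range(n_frames):
        s10 = spec.S10 + i * drift.get("S10", 0.0)
        rot = spec.rotation + i * drift.get("rotation", 0.0)
        scale = 1.0 + i * drift.get("area_scale", 0.0)
        peaks = tuple((hk, a * scale, e) for hk, a, e in spec.eq_peaks)
        fspec = dataclasses.replace(
            spec, S10=s10, rotation=rot, eq_peaks=peaks, seed=spec.seed + i
        )
        img, truth = generate_pattern(fspec)
        path = out_dir / f"{basename}_{i:05d}.tif"
        tifffile.imwrite(path, img.astype(np.float32))
        paths.append(path)
        stack.append(img)
        row = {"frame": i, "S10": s10, "rotation": rot}
        for hk, a, _ in peaks:
            row[f"area_{hk[0]}{hk[1]}"] = a
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / f"{basename}_truth.csv", index=False)
    if hdf5:
        with h5py.File(out_dir / f"{basename}.h5", "w") as f:
            f.create_dataset("data", data=np.stack(stack).astype(np.float32))
    return paths
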