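"""Quadrant folding: average the four Friedel-equivalent quadrants.

By Friedel's law the four quadrants of a fiber pattern carry the same
information, so averaging them doubles the signal-to-noise ratio (summing
raises the signal by a factor of four) and lets intact quadrants fill in
detector gaps: any pixel below the mask threshold in one quadrant is simply
excluded from the average and the remaining copies take over.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError
from .geometry import PatternFrame, rectify

__all__ = ["FoldResult", "fold_quadrants", "reconstruct_full"]


@dataclasses.dataclass
class FoldResult:
    """Result of folding: one averaged quadrant plus the rebuilt full image.

    ``quadrant[0, 0]`` is the pixel adjacent to the pattern center; rows and
    columns grow outward.  ``counts`` records how many of the four quadrant
    copies contributed at each pixel (0-4); where it is 0 the quadrant holds
    the below-threshold sentinel ``mask_threshold - 1``.
    """

    quadrant: np.ndarray
    full_image: np.ndarray
    counts: np.ndarray
    mask_threshold: float
    mode: str = "average"


def fold_quadrants(
    image: np.ndarray,
    frame: PatternFrame,
    mask_threshold: float = 0.0,
    mode: str = "average",
) -> FoldResult:
    """Fold the four quadrants about the pattern center into one.

    The image is rectified first if the frame carries a nonzero rotation,
    then shifted by the sub-pixel remainder so the center lies exactly on a
    pixel-boundary crossing.  The common quadrant size is the largest
    centered rectangle that fits the image.  Each output pixel is the mean
    (``mode="average"``) or sum (``mode="sum"``) of the 1-4 co-located input
    values at or above ``mask_threshold``; accumulation is in float64 and
    cast to float32 so equal contributions fold exactly.
    """
    if mode not in ("average", "sum"):
        raise ValueError(f"mode must be 'average' or 'sum', got {mode!r}")
    img = np.asarray(image, dtype=np.float64)
    if frame.rotation != 0.0:
        img, frame = rectify(img, frame, fill_value=mask_threshold - 1.0)
        img = np.asarray(img, dtype=np.float64)
    cx, cy = frame.center
    h, w = img.shape

    # snap the center onto the nearest pixel-boundary crossing (half-integer
    # coordinates); sx, sy are the integer array split indices
    sx = int(round(cx + 0.5))
    sy = int(round(cy + 0.5))
    dx = (sx - 0.5) - cx
    dy = (sy - 0.5) - cy
    if abs(dx) > 1e-9 or abs(dy) > 1e-9:
        img = ndimage.shift(
            img, (dy, dx), order=1, mode="constant", cval=mask_threshold - 1.0
        )

    qh = min(sy, h - sy)
    qw = min(sx, w - sx)
    if qh < 1 or qw < 1:
        raise GeometryError("pattern center too close to an edge: empty quadrant")

    q_br = img[sy : sy + qh, sx : sx + qw]
    q_bl = img[sy : sy + qh, sx - qw : sx][:, ::-1]
    q_tr = img[sy - qh : sy, sx : sx + qw][::-1, :]
    q_tl = img[sy - qh : sy, sx - qw : sx][::-1, ::-1]
    stack = np.stack([q_tl, q_tr, q_bl, q_br])

    valid = stack >= mask_threshold
    counts = valid.sum(axis=0).astype(np.int16)
    summed = np.where(valid, stack, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        if mode == "average":
            folded = summed / counts
        else:
            folded = summed
    sentinel = mask_threshold - 1.0
    folded = np.where(counts > 0, folded, sentinel).astype(np.float32)

    full = reconstruct_full(folded)
    return FoldResult(folded, full, counts, float(mask_threshold), mode)


def reconstruct_full(quadrant: np.ndarray, counts: np.ndarray | None = None) -> np.ndarray:
    """Mirror a folded quadrant across both axes into a 2h x 2w image.

    The output has exact (bit-identical) four-fold mirror symmetry by
    construction; sentinel pixels (``counts == 0``) propagate to all four
    mirror positions.
    """
    q = np.asarray(quadrant)
    top = np.hstack([q[::-1, ::-1], q[::-1, :]])
    bottom = np.hstack([q[:, ::-1], q])
    return np.vstack([top, bottom])
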