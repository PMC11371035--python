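"""Image I/O and preprocessing.

TIFF (via tifffile) and HDF5 (via h5py) are the supported detector formats;
everything is promoted to 32-bit float on load and written back as 32-bit
float TIFF, so a save/load round trip loses no precision.  Preprocessing
subtracts the instrumental background ("empty cell") exposure and paints
masked-out regions with a sentinel below the mask threshold so every
downstream stage excludes them.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .exceptions import FormatError

__all__ = ["load_image", "load_frames", "save_image", "preprocess", "load_metadata_log"]

_TIFF_SUFFIXES = (".tif", ".tiff")
_HDF5_SUFFIXES = (".h5", ".hdf5", ".hdf")


def _h5_dataset(f: h5py.File) -> h5py.Dataset:
    """First 2-D or 3-D dataset; prefers one named 'data'."""
    if "data" in f and isinstance(f["data"], h5py.Dataset):
        return f["data"]
    found = []

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset) and obj.ndim in (2, 3):
            found.append(obj)

    f.visititems(visit)
    if not found:
        raise FormatError("no 2-D/3-D dataset in HDF5 file")
    return found[0]


def load_frames(path) -> list[np.ndarray]:
    """Load all frames of a file as a list of 2-D float32 arrays."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in _HDF5_SUFFIXES:
            with h5py.File(path, "r") as f:
                arr = np.asarray(_h5_dataset(f))
        elif path.suffix.lower() in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        else:
            raise FormatError(f"unsupported image format: {path.name}")
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read {path.name}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return [arr.astype(np.float32)]
    if arr.ndim == 3:
        return [frame.astype(np.float32) for frame in arr]
    raise FormatError(f"{path.name}: expected 2-D or 3-D data, got {arr.ndim}-D")


def load_image(path, frame: int = 0) -> np.ndarray:
    """Load one frame as a 2-D float32 array (``frame`` indexes HDF5 stacks)."""
    frames = load_frames(path)
    if not 0 <= frame < len(frames):
        raise FormatError(f"{Path(path).name}: no frame {frame} (has {len(frames)})")
    return frames[frame]


def save_image(path, image: np.ndarray) -> Path:
    """Write a 2-D array as a 32-bit float TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))
    return path


def load_metadata_log(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an experiment metadata trace (e.g. muscle force or length vs time).

    The dialect is two numeric columns — time and value — separated by
    commas or whitespace; lines starting with ``#`` are comments.  Returns
    ``(time, value)`` arrays for programmatic alignment with image frames.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", delimiter=None if "," not in path.read_text() else ",")
    except (OSError, ValueError) as exc:
        raise FormatError(f"could not parse metadata log {path.name}: {exc}") from exc
    data = np.atleast_2d(data)
    if data.shape[1] < 2:
        raise FormatError(f"{path.name}: expected two columns (time, value)")
    return data[:, 0], data[:, 1]


def preprocess(
    image: np.ndarray,
    empty_cell: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    mask_threshold: float = 0.0,
) -> np.ndarray:
    """Empty-cell subtraction plus masking.

    Zero-valued mask pixels are set to ``mask_threshold - 1`` so quadrant
    folding, projections and background estimators all treat them exactly
    like detector gaps.
    """
    img = np.asarray(image, dtype=np.float32).copy()
    if empty_cell is not None:
        ec = np.asarray(empty_cell, dtype=np.float32)
        if ec.shape != img.shape:
            raise ValueError("empty-cell image shape differs from image")
        img -= ec
    if mask is not None:
        m = np.asarray(mask)
        if m.shape != img.shape:
            raise ValueError("mask shape differs from image")
        img[m == 0] = mask_threshold - 1.0
    return img
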