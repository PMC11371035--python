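"""Frame stacking to raise SNR: within one experiment and across experiments.

Summing ``k`` statistically equivalent exposures raises the signal by ``k``
and the SNR by ``sqrt(k)``.  ``stack_single`` re-bins a time series within
one directory (consecutive or explicitly listed groups); ``stack_multi``
sums frame-matched images across experiments (matched by the trailing
integer in the file name, or the HDF5 frame index).  Trailing partial
groups are emitted, with their true count in the file name, rather than
silently dropped.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path

import numpy as np

from .fileio import load_frames, save_image
from .geometry import PatternFrame, rectify

logger = logging.getLogger(__name__)

__all__ = ["StackPlan", "stack_single", "stack_multi"]

_TRAILING_INT = re.compile(r"(\d+)(?=\.[^.]+$)")


@dataclasses.dataclass
class StackPlan:
    """How to group and combine frames.

    ``grouping`` is either ``("consecutive", group_size)`` or
    ``("explicit", [[indices], ...])``; explicit groups must be non-empty
    and no frame may appear in more than one group.  ``alignment`` maps a
    frame index to ``(center, rotation)`` overrides applied (via
    rectification) before combining.
    """

    mode: str = "average"  # or "sum"
    grouping: tuple = ("consecutive", 10)
    alignment: dict = dataclasses.field(default_factory=dict)
    template: str = "{base}_{mode}_{start:05d}_to_{stop:05d}_n{count}.tif"

    def __post_init__(self) -> None:
        if self.mode not in ("sum", "average"):
            raise ValueError("mode must be 'sum' or 'average'")
        kind = self.grouping[0]
        if kind == "consecutive":
            if self.grouping[1] < 1:
                raise ValueError("group_size must be >= 1")
        elif kind == "explicit":
            seen: set[int] = set()
            for grp in self.grouping[1]:
                if not grp:
                    raise ValueError("explicit groups must be non-empty")
                if seen & set(grp):
                    raise ValueError("a frame may belong to at most one group")
                seen |= set(grp)
        else:
            raise ValueError(f"unknown grouping kind: {kind!r}")


def _groups(n: int, plan: StackPlan):
    kind = plan.grouping[0]
    if kind == "consecutive":
        g = int(plan.grouping[1])
        return [list(range(i, min(i + g, n))) for i in range(0, n, g)]
    return [list(grp) for grp in plan.grouping[1]]


def _combine(frames: list[np.ndarray], mode: str) -> np.ndarray:
    # float64 accumulation, float32 output: k identical frames sum exactly
    acc = np.sum(np.stack(frames).astype(np.float64), axis=0)
    if mode == "average":
        acc = acc / len(frames)
    return acc.astype(np.float32)


def _list_frames(directory) -> list[Path]:
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".h5", ".hdf5")
        and not p.name.endswith("_truth.csv")
    )
    return files


def stack_single(input_dir, plan: StackPlan, output_dir) -> list[Path]:
    """Re-bin one directory's sequentially named frames in time.

    Frames are ordered by file name; multi-frame files contribute their
    frames in order.  A shape mismatch inside a group skips that group with
    a logged error; a trailing partial group is processed and its count
    encoded in the output name.
    """
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    frames: list[np.ndarray] = []
    for path in _list_frames(input_dir):
        frames.extend(load_frames(path))
    if not frames:
        raise ValueError(f"no frames found in {input_dir}")
    base = Path(input_dir).name or "stack"
    outputs = []
    for grp in _groups(len(frames), plan):
        sel = []
        for i in grp:
            f = frames[i]
            if i in plan.alignment:
                center, rot = plan.alignment[i]
                f, _ = rectify(np.asarray(f), PatternFrame(center, rot))
            sel.append(np.asarray(f))
        shapes = {f.shape for f in sel}
        if len(shapes) != 1:
            logger.error("group %s skipped: mismatched shapes %s", grp, shapes)
            continue
        out = _combine(sel, plan.mode)
        name = plan.template.format(
            base=base, mode=plan.mode, start=grp[0], stop=grp[-1], count=len(grp)
        )
        path = output_dir / name
        save_image(path, out)
        outputs.append(path)
    return outputs


def _index_frames(source) -> dict[int, np.ndarray]:
    """Map frame number -> image for one directory or container file."""
    source = Path(source)
    out: dict[int, np.ndarray] = {}
    if source.is_dir():
        for path in _list_frames(source):
            m = _TRAILING_INT.search(path.name)
            if m is None:
                logger.warning("no frame number in %s; skipped", path.name)
                continue
            frames = load_frames(path)
            if len(frames) == 1:
                out[int(m.group(1))] = frames[0]
            else:
                for j, f in enumerate(frames):
                    out[j] = f
    else:
        for j, f in enumerate(load_frames(source)):
            out[j] = f
    return out


def stack_multi(sources, mode: str, output_dir) -> list[Path]:
    """Sum (or average) frame-matched images across experiments.

    Only frame numbers present in every source are combined (intersection
    semantics); missing indices are logged and skipped.  Raises when no
    index is common to all sources.
    """
    if mode not in ("sum", "average"):
        raise ValueError("mode must be 'sum' or 'average'")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    maps = [_index_frames(s) for s in sources]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    skipped = set().union(*maps) - common
    for idx in sorted(skipped):
        logger.warning("frame %d missing from at least one source; skipped", idx)
    if not common:
        raise ValueError("no frame numbers common to all sources")
    outputs = []
    for idx in sorted(common):
        out = _combine([np.asarray(m[idx]) for m in maps], mode)
        path = output_dir / f"{mode}_frame_{idx:05d}_k{len(maps)}.tif"
        save_image(path, out)
        outputs.append(path)
    return outputs
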