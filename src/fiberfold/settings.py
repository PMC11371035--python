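"""The JSON settings schema for headless batch runs.

Every pipeline parameter can be set from one JSON file; any key missing
falls back to the documented default, and unknown keys are rejected with a
clear error (catching typos before a long batch starts).
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError

from .exceptions import SettingsError
from .geometry import SILVER_BEHENATE_D_NM

__all__ = ["Settings", "load_settings"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CalibrationBlock(_Strict):
    wavelength_nm: float | None = None
    distance_mm: float | None = None
    pixel_size_mm: float | None = None
    center: tuple[float, float] | None = None
    calibrant_d_nm: float = SILVER_BEHENATE_D_NM
    calibration_image: str | None = None


class PreprocessBlock(_Strict):
    empty_cell: str | None = None
    mask: str | None = None
    mask_threshold: float = 0.0


class QuadfoldBlock(_Strict):
    mask_threshold: float = 0.0
    mode: str = "average"
    save_background: bool = False


class BgsubBlock(_Strict):
    method: str = "circular"
    params: dict = {}
    method2: str | None = None
    params2: dict = {}
    merge_radius: float | None = None
    transition_width: float | None = None


class EquatorBlock(_Strict):
    hk_list: list[tuple[int, int]] = [(1, 0), (1, 1), (2, 0), (2, 1), (3, 0)]
    model: str = "gaussian"
    box_height: int | None = None
    box_height_factor: float = 4.0
    reject_threshold: float = 0.10
    orientation_method: str = "azimuthal"
    extra_peaks: list[float] = []


class BoxBlock(_Strict):
    name: str = "box"
    kind: str = "equator_axial"
    anchor: tuple[float, float] | None = None  # None -> pattern center
    length: int = 100
    width: int = 10
    angle: float = 0.0
    peaks: list[float] = []  # initial peak centers, px along the axis
    window_halfwidth: float = 15.0
    background: str = "hull"
    save_trace: bool = False


class TracesBlock(_Strict):
    boxes: list[BoxBlock] = []


class StackBlock(_Strict):
    mode: str = "average"
    group_size: int = 10
    groups: list[list[int]] | None = None


class Settings(_Strict):
    calibration: CalibrationBlock = CalibrationBlock()
    preprocess: PreprocessBlock = PreprocessBlock()
    quadfold: QuadfoldBlock = QuadfoldBlock()
    bgsub: BgsubBlock = BgsubBlock()
    equator: EquatorBlock = EquatorBlock()
    traces: TracesBlock = TracesBlock()
    stack: StackBlock = StackBlock()
    workers: int = 1


def load_settings(path) -> Settings:
    """Parse and validate a settings JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SettingsError(f"cannot read settings {path}: {exc}") from exc
    try:
        return Settings.model_validate(payload)
    except ValidationError as exc:
        raise SettingsError(f"invalid settings {path}: {exc}") from exc
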