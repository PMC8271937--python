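"""File formats and reports: frame directories, landmark/calibration CSVs, JSON.

Video is handled as directories of lexicographically ordered PNG/TIFF frames
(or a single multi-page TIFF), which keeps codec nondeterminism out of the
analysis.  Every report embeds the exact configuration used, because several
outputs (PBI, arch index) are convention-dependent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import __version__
from .calibration import CalibrationWeight
from .core import FormatError, PipelineConfig, PressureImage, as_array

__all__ = [
    "read_frames",
    "write_frames",
    "read_image",
    "write_image",
    "read_calibration_csv",
    "read_landmarks_csv",
    "write_report",
    "read_report",
]

logger = logging.getLogger("plantarkit")

_FRAME_SUFFIXES = (".png", ".tif", ".tiff")


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def read_image(path) -> np.ndarray:
    path = Path(path)
    arr = iio.imread(path)
    if arr.ndim == 3:  # color-coded capture: collapse to intensity
        arr = arr.mean(axis=2)
    logger.info("read %s (sha256:%s)", path, _file_hash(path))
    return arr.astype(float)


def write_image(path, img, bit_depth: int = 8) -> None:
    data = as_array(img)
    if bit_depth == 8:
        out = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    else:
        raise FormatError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def read_frames(path) -> List[np.ndarray]:
    """Ordered frame sequence from a directory of PNG/TIFF files or one multi-page TIFF.

    All frames must share shape and bit depth; mixed depths raise
    :class:`FormatError`, an empty directory :class:`FileNotFoundError`.
    """
    path = Path(path)
    if path.is_file():
        stack = iio.imread(path, index=None)
        if stack.ndim == 2:
            stack = stack[None]
        return [f.astype(float) for f in stack]
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is neither a frame directory nor a file")
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
    if not files:
        raise FileNotFoundError(f"no frame files in {path}")
    frames, shape, dtype = [], None, None
    for f in files:
        arr = iio.imread(f)
        if arr.ndim == 3:
            arr = arr.mean(axis=2).astype(arr.dtype)
        if shape is None:
            shape, dtype = arr.shape, arr.dtype
        elif arr.shape != shape:
            raise FormatError(f"{f.name}: shape {arr.shape} != {shape}")
        elif arr.dtype != dtype:
            raise FormatError(f"{f.name}: bit depth {arr.dtype} != {dtype}")
        logger.info("read %s (sha256:%s)", f, _file_hash(f))
        frames.append(arr.astype(float))
    return frames


def write_frames(directory, frames: Sequence, bit_depth: int = 8) -> List[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, f in enumerate(frames):
        p = directory / f"frame_{i:05d}.png"
        write_image(p, f, bit_depth)
        paths.append(p)
    return paths


def read_calibration_csv(path) -> List[CalibrationWeight]:
    """CSV with columns mass_kg, base_area_m2, mean_intensity."""
    df = pd.read_csv(path)
    needed = {"mass_kg", "base_area_m2", "mean_intensity"}
    if not needed.issubset(df.columns):
        raise FormatError(f"calibration CSV needs columns {sorted(needed)}")
    return [CalibrationWeight(row.mass_kg, row.base_area_m2, row.mean_intensity)
            for row in df.itertuples()]


def read_landmarks_csv(path) -> pd.DataFrame:
    """CSV with columns pair, tile_a, row_a, col_a, tile_b, row_b, col_b."""
    df = pd.read_csv(path)
    needed = {"pair", "tile_a", "row_a", "col_a", "tile_b", "row_b", "col_b"}
    if not needed.issubset(df.columns):
        raise FormatError(f"landmark CSV needs columns {sorted(needed)}")
    return df


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, PressureImage):
        return {"shape": list(obj.shape), "pixel_scale_mm": obj.pixel_scale_mm}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(results: dict, config: Optional[PipelineConfig], path) -> dict:
    """JSON report with a config echo and the library version; returns the payload."""
    payload = {
        "plantarkit_version": __version__,
        "config": dataclasses.asdict(config) if config is not None else None,
        "results": results,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable))
    return payload


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
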