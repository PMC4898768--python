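"""File formats: 16-bit grayscale TIFF, schema-checked CSV, JSON sidecars.

Every numeric result file written by the pipelines carries the producing
configuration hash and master seed so runs can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
    "write_table",
    "read_table",
    "write_json",
    "read_json",
    "config_hash",
    "TRUTH_COLUMNS",
    "DETECTION_COLUMNS",
    "CELL_COLUMNS",
    "UPTAKE_COLUMNS",
]

TRUTH_COLUMNS = ("spot_id", "x", "y", "sigma", "amplitude", "channel2_amplitude")
DETECTION_COLUMNS = ("image_id", "spot_id", "x", "y", "sigma", "amplitude",
                     "local_background", "residual_sd", "p_amplitude", "status",
                     "accepted")
CELL_COLUMNS = ("roi_id", "condition", "experiment_id", "measure", "raw_mean",
                "bg_mean", "net_mean", "pearson_r", "saturated_fraction")
UPTAKE_COLUMNS = ("condition", "experiment_id", "time_min", "replicate", "readout")


def write_image(path: str | Path, image: np.ndarray, bit_depth: int = 16) -> None:
    """Write a grayscale image as 8- or 16-bit TIFF (values rounded and
    clipped to the camera range).  No timestamps are embedded, so identical
    arrays produce byte-identical files."""
    if bit_depth not in (8, 16):
        raise ValueError("TIFF bit_depth must be 8 or 16")
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    arr = np.clip(np.round(np.asarray(image, dtype=float)), 0, 2**bit_depth - 1)
    tifffile.imwrite(str(path), arr.astype(dtype))


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF as float64; rejects non-2D images."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane grayscale TIFF, "
                         f"got shape {arr.shape}")
    return arr.astype(float)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(mask, dtype=np.uint16))


def read_mask(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2D label image")
    return arr.astype(np.int32)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def read_table(path: str | Path, required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a CSV and validate its header against ``required`` columns."""
    table = pd.read_csv(path)
    if required:
        missing = [c for c in required if c not in table.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return table


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(path: str | Path, payload: Any) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def config_hash(payload: Any) -> str:
    """Short stable hash of a configuration object (dataclass or dict)."""
    blob = json.dumps(_jsonable(payload), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
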