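"""Format adapters: TIFF images, CSV tables, JSON reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["read_image", "write_image", "write_table", "read_table", "write_json"]

_SUPPORTED = (np.uint8, np.uint16, np.float32, np.float64)


def read_image(path) -> np.ndarray:
    """Read a single- or multi-channel TIFF; rejects unsupported bit depths."""
    arr = tifffile.imread(str(path))
    if not any(arr.dtype == d for d in _SUPPORTED):
        raise ValueError(
            f"unsupported TIFF bit depth/dtype {arr.dtype} in {path}; "
            "expected uint8, uint16, float32 or float64"
        )
    return arr


def write_image(path, image: np.ndarray, as_uint16: bool = True) -> Path:
    """Write an image as TIFF; float arrays in [0,1] are scaled to 16-bit."""
    path = Path(path)
    arr = np.asarray(image)
    if as_uint16 and np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0.0, 1.0) * 65535).astype(np.uint16)
    tifffile.imwrite(str(path), arr)
    return path


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_jsonable)
    return path


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"cannot serialize {type(obj)}")
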