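"""Reading and writing of volumes and tables.

Volumes are stored as multi-page TIFF stacks, one page per z-slice, with
axis order (z, y, x) throughout the package.  Tables are plain CSV read
into :class:`pandas.DataFrame`.  No timestamps or other volatile metadata
are written, so repeated runs with identical inputs produce byte-identical
files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile


def read_volume(path: str | Path) -> np.ndarray:
    """Read a 3D volume from a multi-page TIFF stack."""
    vol = tifffile.imread(str(path))
    if vol.ndim == 2:
        vol = vol[None]
    if vol.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {vol.shape}")
    return vol


def write_volume(path: str | Path, vol: np.ndarray) -> None:
    """Write a 3D volume as a multi-page TIFF stack (no volatile metadata)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(vol)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {arr.shape}")
    tifffile.imwrite(str(path), arr)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_json(path: str | Path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def frame_path(pattern: str, index: int) -> Path:
    """Resolve a frame-index file pattern such as ``gray_{i:04d}.tif``."""
    try:
        return Path(pattern.format(i=index))
    except (KeyError, IndexError) as exc:
        raise ValueError(f"pattern {pattern!r} must use the placeholder {{i}}") from exc


def tensor_columns(prefix: str) -> list[str]:
    """Column names of the six independent components of a symmetric tensor."""
    return [f"{prefix}_{ij}" for ij in ("zz", "zy", "zx", "yy", "yx", "xx")]


def flatten_tensor(T: np.ndarray) -> list[float]:
    """Six independent components of a symmetric 3x3 tensor, (z,y,x) order."""
    return [T[0, 0], T[0, 1], T[0, 2], T[1, 1], T[1, 2], T[2, 2]]


def unflatten_tensor(components) -> np.ndarray:
    zz, zy, zx, yy, yx, xx = components
    return np.array([[zz, zy, zx], [zy, yy, yx], [zx, yx, xx]], dtype=float)
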