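"""File I/O: TIFF/PNG images, label masks, polygon tables, truth tables.

Conventions: images and masks are single-channel 16-bit TIFF (8-bit PNG
fallback); label masks use background 0 and labels 1..N; polygon
outlines are long-format CSV with columns ``cell_id, vertex_index, x,
y`` (x = column, y = row, 0-based); specs are serialized as flat
``key = value`` TOML next to the outputs they produced.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def read_image(path: Path | str) -> np.ndarray:
    """Read a TIFF or PNG image as a 2-D array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[2] in (3, 4):  # RGB(A) → luminance
        img = img[..., :3].mean(axis=2)
    return img


def write_image(path: Path | str, image: np.ndarray) -> Path:
    """Write a single-channel image; 16-bit TIFF, or 8-bit PNG fallback."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(image, dtype=np.uint16))
    else:
        arr = np.asarray(image)
        if arr.dtype != np.uint8:
            hi = max(int(arr.max()), 1)
            arr = (arr.astype(float) / hi * 255).round().astype(np.uint8)
        iio.imwrite(path, arr)
    return path


def read_polygons_csv(path: Path | str) -> dict[int, list[tuple[float, float]]]:
    """Read cell outlines from CSV (cell_id, vertex_index, x, y)."""
    df = pd.read_csv(path)
    required = {"cell_id", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"polygon CSV must have columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    out: dict[int, list[tuple[float, float]]] = {}
    for cid, sub in df.sort_values(["cell_id", "vertex_index"]).groupby("cell_id"):
        out[int(cid)] = list(zip(sub["x"].astype(float), sub["y"].astype(float)))
    return out


def write_polygons_csv(path: Path | str,
                       polygons: Mapping[int, Any]) -> Path:
    rows = []
    for cid in sorted(polygons):
        for k, (x, y) in enumerate(polygons[cid]):
            rows.append({"cell_id": cid, "vertex_index": k, "x": x, "y": y})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_points_csv(path: Path | str) -> np.ndarray:
    """Read digitized droplet-edge points from CSV with columns x, y."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise ValueError("edge-point CSV must have columns x, y")
    return df[["x", "y"]].to_numpy(float)


def write_spec_toml(path: Path | str, spec: Any) -> Path:
    """Serialize a dataclass spec as flat ``key = value`` TOML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = dataclasses.asdict(spec) if dataclasses.is_dataclass(spec) else dict(spec)
    lines = []
    for k in sorted(d):
        v = d[k]
        if isinstance(v, str):
            lines.append(f'{k} = "{v}"')
        elif isinstance(v, bool):
            lines.append(f"{k} = {str(v).lower()}")
        elif isinstance(v, Mapping):
            inner = ", ".join(f'"{ik}" = {iv}' for ik, iv in sorted(v.items()))
            lines.append(f"{k} = {{{inner}}}")
        elif isinstance(v, (list, tuple)):
            lines.append(f"{k} = [{', '.join(repr(x) for x in v)}]")
        elif v is None:
            lines.append(f'{k} = "none"')
        else:
            lines.append(f"{k} = {v}")
    path.write_text("\n".join(lines) + "\n")
    return path
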