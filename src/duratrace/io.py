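"""File interchange: calibrated TIFF stacks, SWC morphologies, point CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .enhance import ImageStack3D

__all__ = [
    "write_stack_tiff",
    "read_stack_tiff",
    "write_points_csv",
    "read_points_csv",
    "write_swc",
    "read_swc",
    "write_json",
]


def write_stack_tiff(path: str | Path, stack: ImageStack3D) -> None:
    """Multi-page TIFF with the voxel spacing recorded in metadata."""
    dx, dy, dz = stack.spacing
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    tifffile.imwrite(
        str(path),
        np.round(stack.voxels).astype(dtype),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
        imagej=True,
    )


def read_stack_tiff(path: str | Path, spacing=(1.14, 1.14, 1.0)) -> ImageStack3D:
    """Read a multi-page TIFF; spacing from ImageJ metadata when present."""
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        meta = tf.imagej_metadata or {}
        try:
            xres = tf.pages[0].tags["XResolution"].value
            yres = tf.pages[0].tags["YResolution"].value
            dx = xres[1] / xres[0]
            dy = yres[1] / yres[0]
            dz = float(meta.get("spacing", spacing[2]))
            spacing = (dx, dy, dz)
        except KeyError:
            pass
    if arr.ndim == 2:
        arr = arr[None]
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return ImageStack3D(arr.astype(float), spacing=spacing, bit_depth=bit_depth)


def write_points_csv(path: str | Path, points: np.ndarray) -> None:
    pd.DataFrame(np.asarray(points).reshape(-1, 2), columns=["x_um", "y_um"]).to_csv(
        path, index=False
    )


def read_points_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um"]].to_numpy(float)


def write_swc(
    path: str | Path, polylines: list[np.ndarray], radii: list[float] | float
) -> None:
    """Write polylines as an SWC forest (7 columns, 1-based ids, roots -1).

    Termini shared between polylines are fused so trees come out connected.
    """
    if np.isscalar(radii):
        radii = [float(radii)] * len(polylines)
    rows = []
    node_of: dict[tuple, int] = {}

    def key(p):
        return tuple(np.round(np.asarray(p, float), 6))

    next_id = 1
    for poly, r in zip(polylines, radii):
        parent = node_of.get(key(poly[0]), -1)
        start = 0 if parent == -1 else 1
        for p in np.asarray(poly, float)[start:]:
            k = key(p)
            if k in node_of and parent == -1:
                parent = node_of[k]
                continue
            rows.append((next_id, 2, p[0], p[1], p[2], r, parent))
            node_of[k] = next_id
            parent = next_id
            next_id += 1
    with open(path, "w") as f:
        f.write("# id type x y z radius parent (um)\n")
        for i, t, x, y, z, r, par in rows:
            f.write(f"{i} {t} {x:.6g} {y:.6g} {z:.6g} {r:.6g} {par}\n")


def read_swc(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        comment="#",
        sep=r"\s+",
        names=["id", "type", "x", "y", "z", "radius", "parent"],
    )


def write_json(path: str | Path, obj) -> None:
    """Deterministic JSON: sorted keys, plain floats."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=1, default=default))
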