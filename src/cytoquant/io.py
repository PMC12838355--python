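"""TIFF and CSV input/output.

Stacks are written as channel-major multi-page TIFFs (axes ``CZYX``) with
the acquisition geometry and channel names stored as JSON in the image
description, so a stack round-trips without side files.  Ground-truth
masks are written as uint8 0/1 TIFFs with the same layout (channels:
cell, nucleus).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .stack import AcquisitionGeometry, ImageStack


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a CZYX multi-page TIFF with JSON metadata."""
    g = stack.geometry
    meta = {
        "axes": "CZYX",
        "dx_um": g.dx,
        "dy_um": g.dy,
        "dz_um": g.dz,
        "channels": list(stack.channel_names),
        "stack_id": stack.stack_id,
    }
    data = np.moveaxis(stack.voxels, -1, 0)  # (c, z, y, x)
    tifffile.imwrite(
        str(path), data.astype(np.float32), description=json.dumps(meta)
    )


def read_stack(path: str | Path) -> ImageStack:
    """Read a stack written by :func:`write_stack` (or any CZYX TIFF with
    compatible JSON metadata in its description tag)."""
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    if data.ndim == 3:  # single channel
        data = data[None]
    n_c, n_z, n_y, n_x = data.shape
    geometry = AcquisitionGeometry(
        dx=float(meta.get("dx_um", 0.07)),
        dy=float(meta.get("dy_um", meta.get("dx_um", 0.07))),
        dz=float(meta.get("dz_um", 0.19)),
        field_pixels=(n_y, n_x),
        n_slices=n_z,
    )
    names = tuple(meta.get("channels", [f"ch{i}" for i in range(n_c)]))
    return ImageStack(
        voxels=np.moveaxis(data, 0, -1).astype(np.float32),
        geometry=geometry,
        channel_names=names,
        stack_id=str(meta.get("stack_id", Path(path).stem)),
    )


def write_truth_masks(
    path: str | Path, cell_mask_3d: np.ndarray, nucleus_mask_3d: np.ndarray
) -> None:
    """Write ground-truth masks as a 2-channel (cell, nucleus) uint8 TIFF."""
    data = np.stack(
        [cell_mask_3d.astype(np.uint8), nucleus_mask_3d.astype(np.uint8)]
    )
    tifffile.imwrite(
        str(path),
        data,
        description=json.dumps({"axes": "CZYX", "channels": ["cell", "nucleus"]}),
    )


def read_truth_masks(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = tifffile.imread(str(path))
    return data[0].astype(bool), data[1].astype(bool)
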