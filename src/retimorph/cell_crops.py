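"""Per-cell binarized crops (auto-segmentation analogue).

Each counted cell body is exported as a square binary window centred
on its centroid in which every foreground component other than the
cell's own blob has been erased, so the crop shows only the central
counted cell body — the unit used for visual cross-referencing of
morphotype assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .particle_analysis import CellRecord

DEFAULT_WINDOW_PX = 64


@dataclass
class CellCrop:
    """A square binary window containing exactly one cell body."""

    window: np.ndarray  # boolean, square
    cell_id: int
    window_px: int


def extract_crop(
    binary: np.ndarray, record: CellRecord, window_px: int = DEFAULT_WINDOW_PX
) -> CellCrop:
    """Crop a window around a cell's centroid, erasing all neighbours.

    The window is centred on the record's (x, y) centroid, clamped at
    the image borders with zero padding.  Only the connected component
    containing the centroid's cell survives; if the blob touches the
    window edge the window is doubled until it fits (so downstream
    measurements on the crop match the source record).
    """
    binary = np.asarray(binary, dtype=bool)
    h, w = binary.shape
    cx, cy = int(np.floor(record.x)), int(np.floor(record.y))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"centroid ({record.x}, {record.y}) outside grid")

    size = int(window_px)
    while True:
        half = size // 2
        out = np.zeros((size, size), dtype=bool)
        y0, y1 = cy - half, cy - half + size
        x0, x1 = cx - half, cx - half + size
        sy0, sy1 = max(y0, 0), min(y1, h)
        sx0, sx1 = max(x0, 0), min(x1, w)
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = binary[sy0:sy1, sx0:sx1]

        labels, n = ndimage.label(out, structure=np.ones((3, 3), dtype=int))
        if n == 0:
            return CellCrop(out, record.label, size)
        # keep the component under (or nearest to) the centroid
        lcy, lcx = cy - y0, cx - x0
        target = labels[lcy, lcx]
        if target == 0:
            fy, fx = np.nonzero(out)
            d2 = (fy - lcy) ** 2 + (fx - lcx) ** 2
            target = labels[fy[d2.argmin()], fx[d2.argmin()]]
        keep = labels == target
        # grow the window if the kept blob is clipped by it (unless it
        # is clipped by the image border itself)
        ky, kx = np.nonzero(keep)
        at_win_edge = (
            ky.min() == 0 or kx.min() == 0 or ky.max() == size - 1 or kx.max() == size - 1
        )
        clipped_by_image = (
            (y0 <= 0 and ky.min() == sy0 - y0)
            or (x0 <= 0 and kx.min() == sx0 - x0)
            or (y1 >= h and ky.max() == sy1 - y0 - 1)
            or (x1 >= w and kx.max() == sx1 - x0 - 1)
        )
        if at_win_edge and not clipped_by_image and size < 4 * max(h, w):
            size *= 2
            continue
        return CellCrop(keep, record.label, size)


def save_crop(crop: CellCrop, out_dir: str | Path, image_id: str) -> Path:
    """Write a crop as an 8-bit binary PNG named <image>_<cellid>.png."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{image_id}_{crop.cell_id}.png"
    iio.imwrite(path, (crop.window.astype(np.uint8) * 255))
    return path
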