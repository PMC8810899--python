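"""Perivascular-area (PA) analysis.

A pre-traced vessel image is binarized (any non-black pixel is
vessel), a proximity band is built around the vasculature with a
Euclidean distance transform — every pixel within 59.5 px of a vessel
pixel is perivascular — and each counted cell is flagged PA or nPA by
whether its centroid pixel falls inside the band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

DEFAULT_PA_DISTANCE_PX = 59.5


@dataclass
class PAConfig:
    distance_px: float = DEFAULT_PA_DISTANCE_PX
    metric: Literal["euclidean", "chessboard"] = "euclidean"

    def __post_init__(self) -> None:
        if self.distance_px <= 0:
            raise ValueError("distance_px must be > 0")
        if self.metric not in ("euclidean", "chessboard"):
            raise ValueError(f"unknown metric {self.metric!r}")


def binarize_vessels(pixels: np.ndarray) -> np.ndarray:
    """Vessel mask from a traced image: non-black pixels become 1.

    Accepts grayscale (H, W) or RGB (H, W, 3); a pixel is vessel iff
    any channel is > 0.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 3:
        return (pixels > 0).any(axis=2)
    if pixels.ndim == 2:
        return pixels > 0
    raise ValueError("vessel image must be 2-D grayscale or 3-D RGB")


def pa_mask(vessels: np.ndarray, cfg: PAConfig | None = None) -> np.ndarray:
    """Perivascular band: pixels within ``distance_px`` of a vessel.

    Vessel pixels themselves are PA (distance 0).  An empty vessel
    mask yields an empty PA mask.
    """
    cfg = cfg or PAConfig()
    vessels = np.asarray(vessels, dtype=bool)
    if vessels.size == 0:
        raise ValueError("degenerate vessel mask")
    if not vessels.any():
        return np.zeros_like(vessels)
    if cfg.metric == "euclidean":
        dist = ndimage.distance_transform_edt(~vessels)
    else:
        dist = ndimage.distance_transform_cdt(~vessels, metric="chessboard")
    return dist <= cfg.distance_px


def _round_half_away(v: float) -> int:
    return int(np.floor(v + 0.5)) if v >= 0 else -int(np.floor(-v + 0.5))


def classify_pa(records: pd.DataFrame, pa: np.ndarray) -> pd.Series:
    """PA flag per cell: True iff the rounded centroid pixel is PA.

    ``records`` must expose centroid columns ``x`` and ``y`` (px);
    rounding is half-away-from-zero.  Raises on out-of-bounds
    centroids.
    """
    pa = np.asarray(pa, dtype=bool)
    h, w = pa.shape
    flags = []
    for _, row in records.iterrows():
        x, y = float(row["x"]), float(row["y"])
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"centroid ({x}, {y}) outside grid")
        # rounding may push a far-edge centroid one past the last pixel
        px = min(_round_half_away(x), w - 1)
        py = min(_round_half_away(y), h - 1)
        flags.append(bool(pa[py, px]))
    return pd.Series(flags, index=records.index, name="pa")
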