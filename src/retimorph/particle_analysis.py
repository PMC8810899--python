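"""Particle detection and the 34-parameter morphometric record.

The analogue of the classical 'Analyse Particles' step: cell bodies
are 8-connected foreground components, each measured into a canonical
record of 34 morphological and spatial parameters (intensity
statistics, centroids, bounding box, fitted ellipse, circularity,
Feret diameters, solidity, and the Feret's diameter ratio
FDR = F_max / F_min used to separate rod-shaped from other bodies).

Conventions: 0-based coordinates, x = column, y = row; areas in px^2
with micrometre conversions via the image scale; the convex hull is
taken over the pixel-corner polygon (each pixel is a unit square) so
single pixels have positive extent; Feret angles are degrees CCW from
the +x axis in [0, 180).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .imaging_core import Image

#: fixed column order of the morphometric feature table
FEATURE_COLUMNS = [
    "area",
    "mean",
    "stddev",
    "mode",
    "min",
    "max",
    "median",
    "skewness",
    "kurtosis",
    "integrated_density",
    "raw_integrated_density",
    "x",
    "y",
    "xm",
    "ym",
    "perimeter",
    "bx",
    "by",
    "width",
    "height",
    "major",
    "minor",
    "angle",
    "circularity",
    "feret_max",
    "feret_min",
    "feret_angle",
    "feret_x",
    "feret_y",
    "aspect_ratio",
    "roundness",
    "solidity",
    "convex_area",
    "fdr",
]

N_PARAMETERS = len(FEATURE_COLUMNS)  # 34


@dataclass
class Particle:
    """One 8-connected foreground component."""

    label: int
    xs: np.ndarray  # column indices
    ys: np.ndarray  # row indices

    @property
    def area(self) -> int:
        return self.xs.size


@dataclass
class CellRecord:
    """The 34-parameter morphometric vector of one cell body.

    Spatial quantities are in pixels (px, px^2); ``area_um2`` and the
    Feret diameters in micrometres are derived via the image scale.
    """

    label: int
    values: dict

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.values]
        if missing:
            raise ValueError(f"CellRecord missing parameters: {missing}")

    def __getattr__(self, name: str):
        values = object.__getattribute__(self, "__dict__").get("values", {})
        if name in values:
            return values[name]
        raise AttributeError(name)

    def as_series(self) -> pd.Series:
        s = pd.Series({c: self.values[c] for c in FEATURE_COLUMNS})
        s["label"] = self.label
        return s


def find_particles(
    binary: np.ndarray,
    min_area: float = 20.0,
    max_area: float = np.inf,
    exclude_edges: bool = True,
) -> list[Particle]:
    """Detect 8-connected components with area and edge filters.

    Components with ``min_area <= area <= max_area`` are kept;
    components touching the image border are removed iff
    ``exclude_edges``.  Labels are assigned in raster order of each
    component's first pixel.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0 or not binary.any():
        return []
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    h, w = binary.shape
    particles: list[Particle] = []
    slices = ndimage.find_objects(labels)
    # relabel in raster order of first pixel
    order = []
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        sub = labels[sl] == lab
        ys, xs = np.nonzero(sub)
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        first = ys[0] * w + xs[0]
        order.append((first, xs, ys))
    order.sort(key=lambda t: t[0])
    next_label = 1
    for _, xs, ys in order:
        area = xs.size
        if not (min_area <= area <= max_area):
            continue
        if exclude_edges and (
            xs.min() == 0 or ys.min() == 0 or xs.max() == w - 1 or ys.max() == h - 1
        ):
            continue
        particles.append(Particle(next_label, xs, ys))
        next_label += 1
    return particles


# ---------------------------------------------------------------------------
# convex hull and Feret diameters
# ---------------------------------------------------------------------------


def corner_hull(p: Particle) -> np.ndarray:
    """Convex hull vertices of the particle's pixel-corner polygon.

    Each pixel (x, y) contributes its four unit-square corners, so the
    hull of a single pixel is the unit square.  Returns an (m, 2)
    array of (x, y) vertices in counter-clockwise order.
    """
    xs, ys = p.xs, p.ys
    corners = np.concatenate(
        [
            np.stack([xs, ys], axis=1),
            np.stack([xs + 1, ys], axis=1),
            np.stack([xs, ys + 1], axis=1),
            np.stack([xs + 1, ys + 1], axis=1),
        ]
    ).astype(float)
    corners = np.unique(corners, axis=0)
    if corners.shape[0] < 3:
        raise ValueError("degenerate particle")
    hull = ConvexHull(corners)
    return corners[hull.vertices]


def feret_diameters(p: Particle) -> tuple[float, float, float, float, float]:
    """Feret's maximum and minimum diameters of a particle.

    F_max is the greatest distance between two parallel tangents — the
    maximum pairwise distance between convex-hull vertices of the
    pixel-corner polygon.  F_min is the minimum caliper width, computed
    exactly by rotating calipers: the minimum over hull edges of the
    maximum distance of any vertex from that edge's supporting line.

    Returns ``(feret_max, feret_min, feret_angle_deg, feret_x,
    feret_y)`` where the angle is that of the F_max chord, degrees CCW
    from +x in [0, 180), and (feret_x, feret_y) is the chord start.
    """
    verts = corner_hull(p)
    m = verts.shape[0]
    # F_max: brute force over hull vertices (hull is small)
    diff = verts[:, None, :] - verts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    fmax = float(np.sqrt(d2[i, j]))
    a, b = verts[i], verts[j]
    dx, dy = b[0] - a[0], b[1] - a[1]
    angle = np.degrees(np.arctan2(-dy, dx)) % 180.0  # CCW in image coords (y down)
    start = a if (a[0], a[1]) <= (b[0], b[1]) else b
    # F_min: rotating calipers over hull edges
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    valid = lengths > 0
    normals = np.stack([-edges[valid, 1], edges[valid, 0]], axis=1) / lengths[
        valid, None
    ]
    # width for each edge: max |(v - vertex_of_edge) . n|
    rel = verts[None, :, :] - verts[valid][:, None, :]
    widths = np.abs(np.einsum("enk,ek->en", rel, normals)).max(axis=1)
    fmin = float(widths.min())
    return fmax, fmin, float(angle), float(start[0]), float(start[1])


def _trace_perimeter(mask: np.ndarray) -> float:
    """Outline length of the largest outer boundary, Moore tracing.

    Walks the outer boundary pixels of an 8-connected mask; steps of
    length 1 between 4-neighbours and sqrt(2) between diagonal
    neighbours.  A single pixel is treated as a unit square
    (perimeter 4); a straight 1-px line of n pixels yields 2(n-1)+2.
    """
    ys, xs = np.nonzero(mask)
    n = xs.size
    if n == 1:
        return 4.0
    padded = np.zeros((mask.shape[0] + 2, mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask
    # start at the first foreground pixel in raster order
    sy, sx = int(ys[0] + 1), int(xs[0] + 1)
    # Moore neighbourhood, clockwise starting from W
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    perimeter = 0.0
    cy, cx = sy, sx
    backtrack = 0  # came from W
    start_state = None
    for _ in range(8 * n + 8):
        found = False
        for k in range(8):
            idx = (backtrack + k) % 8
            dy, dx = nbrs[idx]
            ny, nx = cy + dy, cx + dx
            if padded[ny, nx]:
                step = np.sqrt(2.0) if dy != 0 and dx != 0 else 1.0
                state = (ny, nx, idx)
                if start_state is None:
                    start_state = (cy, cx, None)
                perimeter += step
                # next search starts from the direction opposite the
                # one we arrived from, rotated one step clockwise
                backtrack = (idx + 5) % 8
                cy, cx = ny, nx
                found = True
                break
        if not found:
            return 4.0  # isolated pixel
        if (cy, cx) == (sy, sx) and perimeter > 0:
            break
    return float(perimeter)


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def measure(p: Particle, img: Image) -> CellRecord:
    """Measure the full 34-parameter record of one particle.

    Intensity statistics are taken over the particle's pixels in the
    supplied image; shape statistics come from the pixel set itself.
    """
    xs, ys = p.xs, p.ys
    h, w = img.pixels.shape
    if xs.min() < 0 or ys.min() < 0 or xs.max() >= w or ys.max() >= h:
        raise ValueError("particle outside image bounds")
    vals = img.pixels[ys, xs]
    area = float(xs.size)
    scale = img.scale_um_per_px

    mean = float(vals.mean())
    stddev = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    # mode over 8-bit quantised intensities, ties to the lowest level
    quant = np.clip(np.rint(vals * 255.0), 0, 255).astype(int)
    mode = float(np.bincount(quant, minlength=256).argmax() / 255.0)
    vmin, vmax = float(vals.min()), float(vals.max())
    median = float(np.median(vals))
    if vals.size > 2 and stddev > 0:
        skewness = float(_skew(vals))
        kurt = float(_kurtosis(vals))
    else:
        skewness, kurt = 0.0, 0.0
    raw_intden = float(vals.sum())
    area_um2 = area * scale * scale
    intden = area_um2 * mean

    # centroids: pixel centres at (x + 0.5, y + 0.5)
    cx = float(xs.mean() + 0.5)
    cy = float(ys.mean() + 0.5)
    tot = vals.sum()
    if tot > 0:
        xm = float(((xs + 0.5) * vals).sum() / tot)
        ym = float(((ys + 0.5) * vals).sum() / tot)
    else:
        xm, ym = cx, cy

    bx, by = float(xs.min()), float(ys.min())
    bw, bh = float(xs.max() - xs.min() + 1), float(ys.max() - ys.min() + 1)

    # ellipse with the same second central moments (normalised to area)
    mu_xx = float(((xs - xs.mean()) ** 2).mean()) + 1.0 / 12.0
    mu_yy = float(((ys - ys.mean()) ** 2).mean()) + 1.0 / 12.0
    mu_xy = float(((xs - xs.mean()) * (ys - ys.mean())).mean())
    common = np.sqrt((mu_xx - mu_yy) ** 2 + 4.0 * mu_xy**2)
    lam1 = (mu_xx + mu_yy + common) / 2.0
    lam2 = (mu_xx + mu_yy - common) / 2.0
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    # rescale so the ellipse area matches the particle area
    if major > 0 and minor > 0:
        k = np.sqrt(area / (np.pi * major * minor / 4.0))
        major *= k
        minor *= k
    if common == 0:
        ell_angle = 0.0
    else:
        ell_angle = np.degrees(0.5 * np.arctan2(-2.0 * mu_xy, mu_xx - mu_yy)) % 180.0

    # crop mask for the boundary walk
    sub = np.zeros((int(bh), int(bw)), dtype=bool)
    sub[ys - ys.min(), xs - xs.min()] = True
    perimeter = _trace_perimeter(sub)
    circularity = min(4.0 * np.pi * area / perimeter**2, 1.0) if perimeter > 0 else 1.0

    fmax, fmin, fangle, fx, fy = feret_diameters(p)
    hull = corner_hull(p)
    convex_area = _polygon_area(hull)
    solidity = min(area / convex_area, 1.0)
    aspect = major / minor if minor > 0 else np.inf
    roundness = 4.0 * area / (np.pi * major**2) if major > 0 else 1.0
    fdr = fmax / fmin

    values = {
        "area": area,
        "mean": mean,
        "stddev": stddev,
        "mode": mode,
        "min": vmin,
        "max": vmax,
        "median": median,
        "skewness": skewness,
        "kurtosis": kurt,
        "integrated_density": intden,
        "raw_integrated_density": raw_intden,
        "x": cx,
        "y": cy,
        "xm": xm,
        "ym": ym,
        "perimeter": perimeter,
        "bx": bx,
        "by": by,
        "width": bw,
        "height": bh,
        "major": major,
        "minor": minor,
        "angle": ell_angle,
        "circularity": circularity,
        "feret_max": fmax,
        "feret_min": fmin,
        "feret_angle": fangle,
        "feret_x": fx,
        "feret_y": fy,
        "aspect_ratio": aspect,
        "roundness": roundness,
        "solidity": solidity,
        "convex_area": convex_area,
        "fdr": fdr,
    }
    return CellRecord(label=p.label, values=values)


def measure_all(particles: list[Particle], img: Image) -> list[CellRecord]:
    return [measure(p, img) for p in particles]


def records_to_frame(records: list[CellRecord], image_id: str = "") -> pd.DataFrame:
    """Feature table: one row per cell, 34 named columns + label (+ image id)."""
    if not records:
        df = pd.DataFrame(columns=["label"] + FEATURE_COLUMNS)
    else:
        df = pd.DataFrame([r.as_series() for r in records])
        df = df[["label"] + FEATURE_COLUMNS]
    if image_id:
        df.insert(0, "image_id", image_id)
    return df


def feret_um(record: CellRecord, scale_um_per_px: float) -> float:
    """F_max of a record converted to micrometres."""
    return record.feret_max * scale_um_per_px


def overlay(img: Image, particles: list[Particle]) -> np.ndarray:
    """RGB overlay: particle outlines and the original image underneath.

    Boundary pixels (foreground pixels 4-adjacent to background) are
    drawn in red.  Returns an (H, W, 3) uint8 array.
    """
    base = img.pixels
    lo, hi = base.min(), base.max()
    norm = (base - lo) / (hi - lo) if hi > lo else np.zeros_like(base)
    rgb = np.stack([norm, norm, norm], axis=2)
    mask = np.zeros(base.shape, dtype=bool)
    for p in particles:
        mask[p.ys, p.xs] = True
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    outline = mask & ~interior
    rgb[outline] = [1.0, 0.0, 0.0]
    return (rgb * 255).astype(np.uint8)
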