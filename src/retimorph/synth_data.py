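"""Seeded synthetic wholemount-retina generator with ground truth.

Emulates Iba-1-like fluorescence images: five parametric cell-body
morphotypes with thin processes, curvilinear vessels, smooth uneven
background and Gaussian noise, plus a per-cell ground-truth table
(centroids, generating labels, shape parameters, perivascular flags).
Every output is reproducible from (seed, parameter set) alone.

Body geometry per morphotype (micrometre scales, converted to pixels
at 0.636 um/px):

- ramified:       small disc, diameter ~ U(5, 11) um, long thin
                  processes; measured F_max stays below the 13.201 um
                  ramified cut-off.
- hyper-ramified: lobular body — an ellipse with scalloped boundary
                  lobes — F_max ~ U(15, 25) um, FDR ~ U(1.5, 2.7),
                  rough outline (low circularity), many processes.
- activated:      ellipse with broad shallow concave bites, F_max ~
                  U(14, 22) um, FDR ~ U(1.5, 2.7), smooth-ish outline
                  (circularity >= 0.6) but reduced solidity, few short
                  processes.
- rod:            plain ellipse, axis ratio ~ U(3.3, 5.5), major ~
                  U(18, 28) um, bipolar processes.
- amoeboid:       near-circular smooth body, F_max ~ U(15, 24) um,
                  solidity >= 0.93, no processes.

The FDR ranges of hyper-ramified ((1.5, 2.7)) and rod ((3.3, 5.5))
leave a symmetric gap around 3, so the midpoint of the two measured
FDR distributions recovers the rod/hyper-ramified elongation cut-off.
Caliper targets are compensated for the ~1 px widening of the
pixel-corner convex hull so that *measured* Feret statistics match the
stated ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_core import DEFAULT_SCALE_UM_PER_PX, Image
from .morphotype import LABEL_ORDER, MorphotypeLabel
from .particle_analysis import FEATURE_COLUMNS
from .perivascular import DEFAULT_PA_DISTANCE_PX

#: measurement bias of the pixel-corner hull relative to the continuous
#: shape: rasterisation truncates the tips of the long axis (net bias
#: near zero) but widens the short caliper by nearly a pixel
_FMAX_BIAS_PX = 0.3
_FMIN_BIAS_PX = 0.85


@dataclass
class ShapeSpec:
    """Per-morphotype body-geometry parameter ranges (um scales)."""

    ramified_diameter_um: tuple[float, float] = (5.0, 11.0)
    hyper_fmax_um: tuple[float, float] = (15.0, 25.0)
    hyper_fdr: tuple[float, float] = (1.5, 2.7)
    hyper_min_area_um2: float = 70.0
    activated_fmax_um: tuple[float, float] = (14.0, 22.0)
    activated_fdr: tuple[float, float] = (1.5, 2.7)
    rod_major_um: tuple[float, float] = (18.0, 28.0)
    rod_ratio: tuple[float, float] = (3.3, 5.5)
    amoeboid_fmax_um: tuple[float, float] = (15.0, 24.0)
    amoeboid_ratio: tuple[float, float] = (1.0, 1.15)
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX


@dataclass
class CellStamp:
    """One rendered cell: body mask, intensity patch and parameters."""

    body: np.ndarray       # boolean body mask
    intensity: np.ndarray  # float intensities (body + processes)
    label: MorphotypeLabel
    params: dict


def _grid(extent_px: float) -> tuple[np.ndarray, np.ndarray, int]:
    n = int(np.ceil(extent_px)) * 2 + 3
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    return xx - c, yy - c, n


def _rotate(xx: np.ndarray, yy: np.ndarray, theta: float):
    ct, st = np.cos(theta), np.sin(theta)
    return ct * xx + st * yy, -st * xx + ct * yy


def _crop_to_content(mask: np.ndarray, *others: np.ndarray):
    ys, xs = np.nonzero(mask)
    sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
    return (mask[sl], *[o[sl] for o in others])


def _ellipse_mask(a: float, b: float, theta: float) -> np.ndarray:
    xx, yy, _ = _grid(max(a, b))
    u, v = _rotate(xx, yy, theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _shape_stats(mask: np.ndarray) -> tuple[float, float, float, float]:
    """(fdr, circularity, solidity, area_px) of a body mask."""
    from .particle_analysis import (
        Particle,
        _polygon_area,
        _trace_perimeter,
        corner_hull,
        feret_diameters,
    )

    ys, xs = np.nonzero(mask)
    p = Particle(0, xs, ys)
    fmax, fmin, *_ = feret_diameters(p)
    area = float(mask.sum())
    perim = _trace_perimeter(mask)
    circ = min(4.0 * np.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    solidity = min(area / _polygon_area(corner_hull(p)), 1.0)
    return fmax / fmin, circ, solidity, area


def _measured_fdr(mask: np.ndarray) -> float:
    return _shape_stats(mask)[0]


def _body_ramified(rng: np.random.Generator, spec: ShapeSpec) -> tuple[np.ndarray, dict]:
    scale = spec.scale_um_per_px
    d_um = rng.uniform(*spec.ramified_diameter_um)
    r = max((d_um / scale - _FMIN_BIAS_PX) / 2.0, 1.5)
    xx, yy, _ = _grid(r)
    mask = xx**2 + yy**2 <= r**2
    return mask, {"fmax_um": d_um, "fdr": 1.0}


def _body_amoeboid(rng: np.random.Generator, spec: ShapeSpec) -> tuple[np.ndarray, dict]:
    scale = spec.scale_um_per_px
    fmax_um = rng.uniform(*spec.amoeboid_fmax_um)
    ratio = rng.uniform(*spec.amoeboid_ratio)
    a = (fmax_um / scale - _FMIN_BIAS_PX) / 2.0
    b = a / ratio
    theta = rng.uniform(0, np.pi)
    return _ellipse_mask(a, b, theta), {"fmax_um": fmax_um, "fdr": ratio}


def _body_rod(rng: np.random.Generator, spec: ShapeSpec) -> tuple[np.ndarray, dict]:
    scale = spec.scale_um_per_px
    lo, hi = spec.rod_ratio
    for _ in range(64):
        major_um = rng.uniform(*spec.rod_major_um)
        ratio = rng.uniform(lo, hi)
        # compensate the per-axis rasterisation bias so the measured
        # FDR approximates the drawn axis ratio
        major = major_um / scale - _FMAX_BIAS_PX
        minor = (major_um / ratio) / scale - _FMIN_BIAS_PX
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(major / 2.0, minor / 2.0, theta)
        if lo - 0.05 <= _measured_fdr(mask) <= hi + 0.05:
            break
    return mask, {"fmax_um": major_um, "fdr": ratio}


def _body_hyper(rng: np.random.Generator, spec: ShapeSpec) -> tuple[np.ndarray, dict]:
    scale = spec.scale_um_per_px
    lo, hi = spec.hyper_fdr
    for _ in range(64):
        fmax_um = rng.uniform(*spec.hyper_fmax_um)
        fdr = rng.uniform(lo, hi)
        fmin_um = fmax_um / fdr
        # keep the implied body comfortably above the hyper area bound
        if 0.60 * np.pi / 4.0 * fmax_um * fmin_um < spec.hyper_min_area_um2:
            continue
        half_l = (fmax_um / scale - _FMAX_BIAS_PX) / 2.0
        half_w = (fmin_um / scale - _FMIN_BIAS_PX) / 2.0
        r_lobe = 0.40 * half_w
        a0, b0 = half_l - r_lobe, half_w - r_lobe
        theta = rng.uniform(0, np.pi)
        xx, yy, _ = _grid(half_l)
        u, v = _rotate(xx, yy, theta)
        # full core ellipse keeps every caliper width near 2*half_w
        mask = (u / a0) ** 2 + (v / b0) ** 2 <= 1.0
        # lobes anchored at both ends of each axis pin the extreme
        # points, hence the Feret calipers; extra lobes in between
        anchor = [0.0, np.pi, np.pi / 2, -np.pi / 2]
        extra = list(rng.uniform(0, 2 * np.pi, int(rng.integers(3, 6))))
        for ph in anchor + extra:
            cx, cy = a0 * np.cos(ph), b0 * np.sin(ph)
            rk = r_lobe if ph in anchor else r_lobe * rng.uniform(0.8, 1.0)
            mask |= (u - cx) ** 2 + (v - cy) ** 2 <= rk**2
        # notches between lobes roughen the outline (high perimeter,
        # low solidity) without moving the extreme points
        n_notch = int(rng.integers(5, 8))
        for ph in rng.uniform(0, 2 * np.pi, n_notch):
            ex, ey = a0 * np.cos(ph), b0 * np.sin(ph)
            r_n = r_lobe * rng.uniform(0.55, 0.8)
            mask &= (u - ex) ** 2 + (v - ey) ** 2 > r_n**2
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
        m_fdr, m_circ, m_sol, m_area = _shape_stats(mask)
        if not (
            lo - 0.02 <= m_fdr <= hi
            and m_circ <= 0.50
            and m_sol <= 0.88
            and m_area * scale**2 >= spec.hyper_min_area_um2 * 0.9
        ):
            continue
        # the lobular outline must survive mild morphological smoothing
        # (detection pipelines open the mask): still one component with
        # nearly the same long caliper and a rough outline
        opened = ndimage.binary_opening(
            mask, structure=ndimage.generate_binary_structure(2, 1)
        )
        _, n_open = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
        if n_open != 1:
            continue
        o_fdr, o_circ, o_sol, o_area = _shape_stats(opened)
        if o_area >= 0.92 * m_area and o_circ <= 0.55 and lo - 0.1 <= o_fdr <= hi + 0.1:
            break
    return mask, {"fmax_um": fmax_um, "fdr": fdr}


def _body_activated(rng: np.random.Generator, spec: ShapeSpec) -> tuple[np.ndarray, dict]:
    scale = spec.scale_um_per_px
    lo, hi = spec.activated_fdr
    for _ in range(64):
        fmax_um = rng.uniform(*spec.activated_fmax_um)
        fdr = rng.uniform(lo, hi)
        a = (fmax_um / scale - _FMAX_BIAS_PX) / 2.0
        b = (fmax_um / fdr / scale - _FMIN_BIAS_PX) / 2.0
        theta = rng.uniform(0, np.pi)
        xx, yy, _ = _grid(a)
        u, v = _rotate(xx, yy, theta)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        # broad shallow bites on the shoulders: reduce solidity while
        # keeping the outline smooth (circularity stays >= 0.6) and
        # leaving the extreme points (both Feret calipers) intact
        n_bites = int(rng.integers(3, 5))
        for k in range(n_bites):
            side = 1 if k % 2 == 0 else -1
            ph = rng.uniform(0.8, 1.3) * side + (np.pi if k >= 2 else 0.0)
            ex, ey = a * np.cos(ph), b * np.sin(ph)
            nx, ny = np.cos(ph) / a, np.sin(ph) / b
            nn = np.hypot(nx, ny)
            nx, ny = nx / nn, ny / nn
            r_bite = rng.uniform(1.8, 2.6) * b
            depth = rng.uniform(0.30, 0.45) * b
            cx, cy = ex + nx * (r_bite - depth), ey + ny * (r_bite - depth)
            mask &= (u - cx) ** 2 + (v - cy) ** 2 > r_bite**2
        # keep the largest component in case a bite disconnects a sliver
        lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n > 1:
            sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = lab == (1 + int(np.argmax(sizes)))
        m_fdr, m_circ, m_sol, _ = _shape_stats(mask)
        if lo - 0.05 <= m_fdr <= 2.95 and m_circ >= 0.63 and m_sol <= 0.83:
            break
    return mask, {"fmax_um": fmax_um, "fdr": fdr}


_BODY_BUILDERS = {
    MorphotypeLabel.RAMIFIED: _body_ramified,
    MorphotypeLabel.HYPER_RAMIFIED: _body_hyper,
    MorphotypeLabel.ACTIVATED: _body_activated,
    MorphotypeLabel.ROD: _body_rod,
    MorphotypeLabel.AMOEBOID: _body_amoeboid,
}

#: number and length (um) of processes per morphotype
_PROCESS_SPEC = {
    MorphotypeLabel.RAMIFIED: (5, (12.0, 25.0)),
    MorphotypeLabel.HYPER_RAMIFIED: (8, (10.0, 22.0)),
    MorphotypeLabel.ACTIVATED: (3, (4.0, 9.0)),
    MorphotypeLabel.ROD: (2, (10.0, 20.0)),
    MorphotypeLabel.AMOEBOID: (0, (0.0, 0.0)),
}


def _draw_processes(
    body: np.ndarray, label: MorphotypeLabel, rng: np.random.Generator, scale: float
) -> np.ndarray:
    """Thin (1 px) curved polylines radiating from the body boundary.

    ``body`` is the full-size (already padded) stamp mask; returns an
    intensity canvas of the same shape.
    """
    canvas = np.zeros(body.shape, dtype=float)
    n_proc, (lo, hi) = _PROCESS_SPEC[label]
    if n_proc == 0:
        return canvas
    ys, xs = np.nonzero(body)
    cy, cx = ys.mean(), xs.mean()
    h, w = body.shape
    if label is MorphotypeLabel.ROD:
        # bipolar: along the body's principal axis
        mu_xx = ((xs - cx) ** 2).mean()
        mu_yy = ((ys - cy) ** 2).mean()
        mu_xy = ((xs - cx) * (ys - cy)).mean()
        base = 0.5 * np.arctan2(2 * mu_xy, mu_xx - mu_yy)
        angles = [base, base + np.pi]
    else:
        angles = list(rng.uniform(0, 2 * np.pi, n_proc))
    for ang in angles:
        length = rng.uniform(lo, hi) / scale
        curve = rng.uniform(-0.6, 0.6)
        # start on the body boundary along this direction
        rr = 1.0
        while True:
            py, px = cy + rr * np.sin(ang), cx + rr * np.cos(ang)
            iy, ix = int(round(py)), int(round(px))
            if not (0 <= iy < h and 0 <= ix < w) or not body[iy, ix]:
                break
            rr += 1.0
        t = np.linspace(0, 1, max(int(length * 3), 8))
        aa = ang + curve * t
        pxs = px + np.cumsum(np.cos(aa)) * (length / t.size)
        pys = py + np.cumsum(np.sin(aa)) * (length / t.size)
        ii = np.round(pys).astype(int)
        jj = np.round(pxs).astype(int)
        ok = (ii >= 0) & (ii < h) & (jj >= 0) & (jj < w)
        canvas[ii[ok], jj[ok]] = rng.uniform(0.35, 0.5)
    return canvas


def make_cell(
    label: MorphotypeLabel | str,
    rng: np.random.Generator,
    spec: ShapeSpec | None = None,
) -> CellStamp:
    """Render one cell stamp (body mask + intensity patch).

    The measured F_max, FDR and solidity of the body fall in the
    morphotype's declared ranges up to pixel discretisation.
    """
    label = MorphotypeLabel(label)
    spec = spec or ShapeSpec()
    core, params = _BODY_BUILDERS[label](rng, spec)
    core = _crop_to_content(core)[0]
    # pad the stamp so processes radiating beyond the body fit
    n_proc, (_, proc_hi) = _PROCESS_SPEC[label]
    pad = int(np.ceil(proc_hi / spec.scale_um_per_px)) + 2 if n_proc else 1
    body = np.zeros((core.shape[0] + 2 * pad, core.shape[1] + 2 * pad), dtype=bool)
    body[pad : pad + core.shape[0], pad : pad + core.shape[1]] = core
    processes = _draw_processes(body, label, rng, spec.scale_um_per_px)
    base = rng.uniform(0.75, 0.95)
    texture = rng.normal(0.0, 0.02, body.shape)
    body_intensity = np.where(body, np.clip(base + texture, 0.55, 1.0), 0.0)
    intensity = np.maximum(body_intensity, np.where(body, 0.0, processes))
    params = dict(params, label=label.value)
    return CellStamp(body, intensity, label, params)


# ---------------------------------------------------------------------------
# vessels, background, full retina
# ---------------------------------------------------------------------------


@dataclass
class VesselSpec:
    n_vessels: int = 3
    width_px: float = 4.0
    wiggle: float = 0.15  # fractional lateral wander


def make_vessels(
    shape: tuple[int, int], spec: VesselSpec, rng: np.random.Generator
) -> np.ndarray:
    """Curvilinear vessel mask: smooth paths crossing the image."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_vessels):
        horizontal = rng.random() < 0.5
        n_pts = max(h, w) * 2
        t = np.linspace(0, 1, n_pts)
        amp = spec.wiggle * (h if horizontal else w)
        k1, k2 = rng.uniform(1, 2.5), rng.uniform(2.5, 5)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        wander = amp * (np.sin(2 * np.pi * k1 * t + p1) * 0.7
                        + np.sin(2 * np.pi * k2 * t + p2) * 0.3)
        offset = rng.uniform(0.15, 0.85)
        if horizontal:
            cx = t * (w - 1)
            cy = offset * h + wander
        else:
            cy = t * (h - 1)
            cx = offset * w + wander
        r = spec.width_px / 2.0
        ri = int(np.ceil(r))
        for px, py in zip(cx, cy):
            ix, iy = int(round(px)), int(round(py))
            y0, y1 = max(iy - ri, 0), min(iy + ri + 1, h)
            x0, x1 = max(ix - ri, 0), min(ix + ri + 1, w)
            if y0 >= y1 or x0 >= x1:
                continue
            sub = (yy[y0:y1, x0:x1] - py) ** 2 + (xx[y0:y1, x0:x1] - px) ** 2
            mask[y0:y1, x0:x1] |= sub <= r * r
    return mask


def _background(
    shape: tuple[int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth uneven staining: sum of 2-4 low-frequency sinusoids."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    bg = np.zeros(shape, dtype=float)
    n_waves = rng.integers(2, 5)
    for _ in range(n_waves):
        fx = rng.uniform(0.3, 1.5) / w
        fy = rng.uniform(0.3, 1.5) / h
        phase = rng.uniform(0, 2 * np.pi)
        bg += np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
    bg = bg / n_waves  # in [-1, 1]
    return 0.12 + amplitude * (bg + 1.0) / 2.0


def _pa_flag_bruteforce(
    cx: float, cy: float, vessel_mask: np.ndarray, distance_px: float
) -> bool:
    """PA membership by direct minimum distance to every vessel pixel.

    Independent of the distance-transform path: the centroid is rounded
    half-away-from-zero to its pixel and compared against all vessel
    pixel centres.
    """
    vy, vx = np.nonzero(vessel_mask)
    if vy.size == 0:
        return False
    px = int(np.floor(cx + 0.5))
    py = int(np.floor(cy + 0.5))
    d = np.hypot(vx - px, vy - py)
    return bool(d.min() <= distance_px)


def make_retina(
    n_per_type: int | dict = 8,
    shape: tuple[int, int] = (512, 512),
    noise_sd: float = 0.03,
    background_amplitude: float = 0.08,
    vessel_spec: VesselSpec | None = None,
    shape_spec: ShapeSpec | None = None,
    seed: int = 0,
    max_tries: int = 1000,
) -> tuple[Image, pd.DataFrame, np.ndarray]:
    """Compose a synthetic wholemount retina with ground truth.

    Returns ``(image, truth, vessel_mask)``.  ``truth`` has one row
    per planted cell: centroid (x, y, px), morphotype, target shape
    parameters and the PA flag computed by brute-force distance to the
    vessel mask at the canonical 59.5 px threshold.

    Bodies are placed by rejection sampling with no overlap and a
    margin from the border; a placement failure after ``max_tries``
    raises with a suggestion to lower the density.
    """
    rng = np.random.default_rng(seed)
    spec = shape_spec or ShapeSpec()
    vspec = vessel_spec or VesselSpec()
    h, w = shape
    if isinstance(n_per_type, int):
        n_per_type = {label: n_per_type for label in LABEL_ORDER}
    vessels = make_vessels(shape, vspec, rng)
    canvas = _background(shape, background_amplitude, rng)
    occupied = np.zeros(shape, dtype=bool)
    rows = []
    margin = 8
    for label in LABEL_ORDER:
        for _ in range(int(n_per_type.get(label, 0))):
            stamp = make_cell(label, rng, spec)
            sh, sw = stamp.intensity.shape
            ys, xs = np.nonzero(stamp.body)
            by0, by1 = int(ys.min()), int(ys.max()) + 1
            bx0, bx1 = int(xs.min()), int(xs.max()) + 1
            bh, bw = by1 - by0, bx1 - bx0
            placed = False
            for _try in range(max_tries):
                # position of the body bounding box; processes may spill
                # over other cells' processes but bodies never overlap
                yb = int(rng.integers(margin, h - bh - margin))
                xb = int(rng.integers(margin, w - bw - margin))
                pad_box = occupied[
                    max(yb - 4, 0) : yb + bh + 4, max(xb - 4, 0) : xb + bw + 4
                ]
                if not pad_box.any():
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    "could not place all cells without overlap; lower the "
                    "density (fewer cells or a larger image)"
                )
            occupied[yb : yb + bh, xb : xb + bw] = stamp.body[by0:by1, bx0:bx1] | occupied[
                yb : yb + bh, xb : xb + bw
            ]
            # blend the full stamp, clipped at the canvas edges
            y0, x0 = yb - by0, xb - bx0
            sy0, sx0 = max(y0, 0), max(x0, 0)
            sy1, sx1 = min(y0 + sh, h), min(x0 + sw, w)
            canvas[sy0:sy1, sx0:sx1] = np.maximum(
                canvas[sy0:sy1, sx0:sx1],
                stamp.intensity[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0],
            )
            cx = float(xs.mean() + x0 + 0.5)
            cy = float(ys.mean() + y0 + 0.5)
            rows.append(
                {
                    "x": cx,
                    "y": cy,
                    "morphotype": label.value,
                    "fmax_um_target": stamp.params["fmax_um"],
                    "fdr_target": stamp.params["fdr"],
                    "body_area_px": int(stamp.body.sum()),
                    "pa": _pa_flag_bruteforce(cx, cy, vessels, DEFAULT_PA_DISTANCE_PX),
                }
            )
    noisy = np.clip(canvas + rng.normal(0.0, noise_sd, shape), 0.0, 1.0)
    img = Image(noisy, spec.scale_um_per_px)
    truth = pd.DataFrame(
        rows,
        columns=["x", "y", "morphotype", "fmax_um_target", "fdr_target",
                 "body_area_px", "pa"],
    )
    return img, truth, vessels


# ---------------------------------------------------------------------------
# feature-space shortcut
# ---------------------------------------------------------------------------

#: per-class sampling ranges of the discriminative features:
#: (fmax_um, fdr, solidity, circularity)
_FEATURE_RANGES = {
    MorphotypeLabel.RAMIFIED: ((5.0, 11.0), (1.0, 1.4), (0.90, 0.99), (0.80, 0.95)),
    MorphotypeLabel.HYPER_RAMIFIED: ((15.0, 25.0), (1.5, 2.7), (0.65, 0.88), (0.25, 0.55)),
    MorphotypeLabel.ACTIVATED: ((14.0, 22.0), (1.5, 2.7), (0.72, 0.88), (0.62, 0.80)),
    MorphotypeLabel.ROD: ((18.0, 28.0), (3.3, 5.5), (0.88, 0.97), (0.45, 0.70)),
    MorphotypeLabel.AMOEBOID: ((15.0, 24.0), (1.0, 1.15), (0.93, 0.99), (0.85, 0.97)),
}

#: area fill factor vs the Feret-box ellipse, per class
_FILL_FACTOR = {
    MorphotypeLabel.RAMIFIED: (0.95, 1.0),
    MorphotypeLabel.HYPER_RAMIFIED: (0.60, 0.80),
    MorphotypeLabel.ACTIVATED: (0.75, 0.90),
    MorphotypeLabel.ROD: (0.90, 1.0),
    MorphotypeLabel.AMOEBOID: (0.95, 1.0),
}


def make_feature_table(
    n_per_type: int = 240,
    seed: int = 0,
    spec: ShapeSpec | None = None,
) -> pd.DataFrame:
    """Sample a balanced labelled 34-parameter table directly.

    A feature-space shortcut that bypasses imaging: the
    class-discriminative features (feret_max, fdr, solidity, area,
    circularity) are drawn from the per-morphotype shape ranges; the
    remaining parameters are derived consistently with weak noise.
    Spatial quantities are in pixels at the default 0.636 um/px scale.
    """
    spec = spec or ShapeSpec()
    scale = spec.scale_um_per_px
    rng = np.random.default_rng(seed)
    rows = []
    for label in LABEL_ORDER:
        (fmax_r, fdr_r, sol_r, circ_r) = _FEATURE_RANGES[label]
        fill_r = _FILL_FACTOR[label]
        for _ in range(n_per_type):
            fmax_um = rng.uniform(*fmax_r)
            fdr = rng.uniform(*fdr_r)
            solidity = rng.uniform(*sol_r)
            circ = rng.uniform(*circ_r)
            fmax = fmax_um / scale
            fmin = fmax / fdr
            fill = rng.uniform(*fill_r)
            area = np.pi / 4.0 * fmax * fmin * fill
            convex_area = area / solidity
            perimeter = np.sqrt(4.0 * np.pi * area / circ)
            major = fmax * rng.uniform(0.92, 1.0)
            minor = max(area / (np.pi * major / 4.0), 1.0)
            mean = rng.uniform(0.65, 0.95)
            sd = rng.uniform(0.02, 0.15)
            x = rng.uniform(20, 490)
            y = rng.uniform(20, 490)
            angle = rng.uniform(0, 180)
            bw = abs(fmax * np.cos(np.radians(angle))) + abs(
                fmin * np.sin(np.radians(angle))
            )
            bh = abs(fmax * np.sin(np.radians(angle))) + abs(
                fmin * np.cos(np.radians(angle))
            )
            # detected particles include diluted boundary pixels, so the
            # intensity histogram is left-skewed and heavy-tailed
            vmin = rng.uniform(0.08, 0.6)
            vmax = min(mean + rng.uniform(0.5, 3.0) * sd, 1.0)
            skew = rng.normal(-3.0, 2.5)
            kurt = max(rng.gamma(1.5, 20.0) - 1.0, -1.0)
            rows.append(
                {
                    "area": area,
                    "mean": mean,
                    "stddev": sd,
                    "mode": np.round(np.clip(mean + rng.normal(0, sd), 0, 1) * 255)
                    / 255,
                    "min": vmin,
                    "max": vmax,
                    "median": mean + rng.normal(0, sd / 3),
                    "skewness": skew,
                    "kurtosis": kurt,
                    "integrated_density": area * scale**2 * mean,
                    "raw_integrated_density": area * mean,
                    "x": x,
                    "y": y,
                    "xm": x + rng.normal(0, 0.3),
                    "ym": y + rng.normal(0, 0.3),
                    "perimeter": perimeter,
                    "bx": x - bw / 2,
                    "by": y - bh / 2,
                    "width": bw,
                    "height": bh,
                    "major": major,
                    "minor": minor,
                    "angle": angle,
                    "circularity": circ,
                    "feret_max": fmax,
                    "feret_min": fmin,
                    "feret_angle": rng.uniform(0, 180),
                    "feret_x": x - fmax / 2,
                    "feret_y": y - fmin / 2,
                    "aspect_ratio": major / minor,
                    "roundness": 4.0 * area / (np.pi * major**2),
                    "solidity": solidity,
                    "convex_area": convex_area,
                    "fdr": fdr,
                    "morphotype": label.value,
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["morphotype"])


def save_retina(
    out_dir: str | Path,
    img: Image,
    truth: pd.DataFrame,
    vessels: np.ndarray,
    params: dict | None = None,
) -> dict[str, Path]:
    """Write image TIFF, vessel TIFF, truth CSV and params JSON."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out_dir / "retina.tif",
        "vessels": out_dir / "vessels.tif",
        "truth": out_dir / "truth.csv",
        "params": out_dir / "params.json",
    }
    tifffile.imwrite(paths["image"], (img.pixels * 65535).astype(np.uint16))
    tifffile.imwrite(paths["vessels"], vessels.astype(np.uint8) * 255)
    truth.to_csv(paths["truth"], index=False)
    paths["params"].write_text(json.dumps(params or {}, indent=2, default=str))
    return paths
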