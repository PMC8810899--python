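"""Preprocessing front end of the cell-body counting pipeline.

Operators mirror the classical ImageJ workflow used for wholemount
Iba-1 fluorescence images: despeckle (3x3 median), bright-outlier
removal, gamma adjustment, grayscale attribute filtering (area-opening
top-hat) to flatten uneven staining, and local auto-thresholding with
either the IsoData (iterative intermeans) or the Moments (Tsai
moment-preserving) rule evaluated on a square window around every
pixel.

All operators work on floating-point intensities in [0, 1]; readers
normalise 8/16-bit inputs on load.  The coordinate convention is
0-based, origin top-left, x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.morphology import area_opening

#: default physical scale of the imaging setup (10x lens)
DEFAULT_SCALE_UM_PER_PX = 0.636

#: number of grey levels used for windowed histogram thresholding
N_BINS = 256


@dataclass
class Image:
    """A single-channel 2-D intensity image with physical scale.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities.  Internally float in
        [0, 1]; integer arrays are accepted and normalised by callers.
    scale_um_per_px
        Physical pixel pitch in micrometres per pixel.
    analysed_mask
        Boolean grid marking non-artefact pixels.  Defaults to all-True.
    """

    pixels: np.ndarray
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX
    analysed_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("Image.pixels must be 2-D")
        if self.scale_um_per_px <= 0:
            raise ValueError("scale_um_per_px must be > 0")
        if self.analysed_mask is None:
            self.analysed_mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.analysed_mask = np.asarray(self.analysed_mask, dtype=bool)
            if self.analysed_mask.shape != self.pixels.shape:
                raise ValueError("analysed_mask shape must match pixels shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image":
        """Copy of this image with new pixel data, same scale and mask."""
        return replace(self, pixels=np.asarray(pixels, dtype=float))


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    The classical workflow names the operators but not their numeric
    settings; these defaults are surrogates chosen to work well on the
    synthetic retina images and are all configurable.

    ``outlier_threshold`` is expressed in 8-bit intensity units
    (0-255) for familiarity; it is divided by 255 when applied to the
    internal unit-interval representation.
    """

    gamma: float = 0.8
    despeckle_radius: int = 1           # fixed 3x3 median
    outlier_radius: int = 2
    outlier_threshold: float = 50.0     # 8-bit units, bright outliers
    tophat_area_lambda: int = 10000     # px^2, >> largest cell body
    threshold_method: Literal["moments", "isodata"] = "moments"
    threshold_radius: int = 15
    threshold_min_contrast: float = 0.1  # fraction of the global range

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        for name in ("despeckle_radius", "outlier_radius", "threshold_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tophat_area_lambda < 1:
            raise ValueError("tophat_area_lambda must be >= 1")
        if self.threshold_method not in ("moments", "isodata"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def apply_artefact_mask(img: Image, mask: np.ndarray) -> Image:
    """Zero out artefact pixels and exclude them from analysis.

    Pixels where ``mask`` is False are set to 0 and removed from
    ``analysed_mask``; everything else is untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.pixels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {img.pixels.shape}"
        )
    out = img.pixels.copy()
    out[~mask] = 0.0
    return Image(out, img.scale_um_per_px, img.analysed_mask & mask)


def despeckle(img: Image) -> Image:
    """3x3 median filter (reflect edges), the classical 'Despeckle'."""
    return img.with_pixels(ndimage.median_filter(img.pixels, size=3, mode="reflect"))


def _disc_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (xx * xx + yy * yy) <= radius * radius


def remove_outliers(img: Image, radius: int = 2, threshold: float = 50 / 255) -> Image:
    """Replace bright outliers by the local disc median.

    A pixel is replaced by the median of the disc of the given radius
    iff ``pixel - median > threshold`` (bright outliers only), matching
    the classical 'Remove Outliers' behaviour.  ``threshold`` is in the
    image's own intensity units.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    med = ndimage.median_filter(
        img.pixels, footprint=_disc_footprint(radius), mode="reflect"
    )
    out = np.where(img.pixels - med > threshold, med, img.pixels)
    return img.with_pixels(out)


def adjust_gamma(img: Image, gamma: float) -> Image:
    """Pointwise gamma mapping, monotone and range-preserving.

    Intensities are normalised to [0, 1] over the image's own range,
    mapped ``v -> v**gamma`` and rescaled back, so min and max map to
    themselves for any gamma.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    lo, hi = float(img.pixels.min()), float(img.pixels.max())
    if hi == lo:
        return img.with_pixels(img.pixels.copy())
    v = (img.pixels - lo) / (hi - lo)
    return img.with_pixels(lo + (hi - lo) * v**gamma)


def attribute_tophat(img: Image, area_lambda: int = 10000) -> Image:
    """Grayscale attribute-filter top-hat for background equalisation.

    Returns ``img - area_opening(img, area_lambda)``: bright structures
    of connected area smaller than ``area_lambda`` survive on a
    flattened background, larger-scale staining gradients are removed.
    Output is non-negative.
    """
    if area_lambda < 1:
        raise ValueError("area_lambda must be >= 1")
    opened = area_opening(img.pixels, area_threshold=area_lambda, connectivity=2)
    return img.with_pixels(np.maximum(img.pixels - opened, 0.0))


# ---------------------------------------------------------------------------
# local auto-thresholding
# ---------------------------------------------------------------------------


def _quantise(pixels: np.ndarray, n_bins: int = N_BINS) -> np.ndarray:
    """Map intensities to bin indices 0..n_bins-1 over the global range.

    Binning over the global min/max makes the result invariant to
    affine intensity rescaling (the bin image is unchanged).
    """
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.int64)
    idx = np.floor((pixels - lo) / (hi - lo) * n_bins).astype(np.int64)
    return np.clip(idx, 0, n_bins - 1)


def _local_histograms(bins: np.ndarray, radius: int, n_bins: int) -> np.ndarray:
    """Per-pixel histogram of the (2r+1)-square window, reflect padding.

    Returns array of shape (H, W, n_bins), counts as float32.
    """
    size = 2 * radius + 1
    h, w = bins.shape
    hist = np.empty((h, w, n_bins), dtype=np.float32)
    area = float(size * size)
    for b in range(n_bins):
        frac = ndimage.uniform_filter(
            (bins == b).astype(np.float32), size=size, mode="reflect"
        )
        hist[:, :, b] = np.rint(frac * area)
    return hist


def isodata_threshold_hist(hist: np.ndarray) -> int:
    """IsoData (iterative intermeans) threshold of one histogram.

    Returns the bin index T of the converged threshold; pixels with bin
    index > T are foreground.  A histogram with a single occupied bin
    is degenerate and returns the top bin (all background).
    """
    hist = np.asarray(hist, dtype=float)
    n_bins = hist.size
    occupied = np.nonzero(hist)[0]
    if occupied.size <= 1:
        return n_bins - 1
    lo, hi = int(occupied[0]), int(occupied[-1])
    levels = np.arange(n_bins, dtype=float)
    cum_n = np.cumsum(hist)
    cum_s = np.cumsum(hist * levels)
    t = (lo + hi) // 2
    t = min(max(t, lo), hi - 1)
    for _ in range(256):
        mean_low = cum_s[t] / cum_n[t]
        mean_high = (cum_s[-1] - cum_s[t]) / (cum_n[-1] - cum_n[t])
        t_new = int(np.floor((mean_low + mean_high) / 2.0 + 0.5))
        t_new = min(max(t_new, lo), hi - 1)
        if t_new == t:
            break
        t = t_new
    return t


def moments_threshold_hist(hist: np.ndarray) -> int:
    """Tsai moment-preserving threshold of one histogram.

    Finds the fraction p0 of below-threshold pixels such that the first
    three grey-level moments of the binary image match those of the
    original histogram, then returns the smallest bin index T whose
    cumulative fraction exceeds p0.  Degenerate histograms return the
    top bin (all background).
    """
    hist = np.asarray(hist, dtype=float)
    n_bins = hist.size
    if np.count_nonzero(hist) <= 1:
        return n_bins - 1
    p = hist / hist.sum()
    levels = np.arange(n_bins, dtype=float)
    m1 = float(np.sum(levels * p))
    m2 = float(np.sum(levels**2 * p))
    m3 = float(np.sum(levels**3 * p))
    cd = m2 - m1 * m1
    if cd <= 0:
        return n_bins - 1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        return n_bins - 1
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        return n_bins - 1
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    above = np.nonzero(cum > p0)[0]
    return int(above[0]) if above.size else n_bins - 1


def _isodata_thresholds(hist: np.ndarray) -> np.ndarray:
    """Vectorised per-pixel IsoData thresholds from local histograms."""
    h, w, n_bins = hist.shape
    levels = np.arange(n_bins, dtype=np.float32)
    cum_n = np.cumsum(hist, axis=2)
    cum_s = np.cumsum(hist * levels, axis=2)
    tot_n = cum_n[:, :, -1]
    tot_s = cum_s[:, :, -1]
    occ = hist > 0
    lo = np.argmax(occ, axis=2).astype(np.int64)
    hi = n_bins - 1 - np.argmax(occ[:, :, ::-1], axis=2).astype(np.int64)
    degenerate = lo >= hi
    t = np.clip((lo + hi) // 2, lo, np.maximum(hi - 1, lo))
    for _ in range(256):
        n_low = np.take_along_axis(cum_n, t[:, :, None], axis=2)[:, :, 0]
        s_low = np.take_along_axis(cum_s, t[:, :, None], axis=2)[:, :, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_low = s_low / n_low
            mean_high = (tot_s - s_low) / (tot_n - n_low)
        t_new = np.floor((mean_low + mean_high) / 2.0 + 0.5)
        t_new = np.where(np.isfinite(t_new), t_new, t).astype(np.int64)
        t_new = np.clip(t_new, lo, np.maximum(hi - 1, lo))
        if np.array_equal(t_new, t):
            break
        t = t_new
    t[degenerate] = n_bins - 1
    return t


def _moments_thresholds(hist: np.ndarray) -> np.ndarray:
    """Vectorised per-pixel Tsai moment thresholds from local histograms."""
    h, w, n_bins = hist.shape
    levels = np.arange(n_bins, dtype=np.float64)
    tot = hist.sum(axis=2)
    p = hist / tot[:, :, None]
    m1 = p @ levels
    m2 = p @ levels**2
    m3 = p @ levels**3
    cd = m2 - m1 * m1
    degenerate = (hist > 0).sum(axis=2) <= 1
    with np.errstate(divide="ignore", invalid="ignore"):
        c0 = (-m2 * m2 + m1 * m3) / cd
        c1 = (-m3 + m2 * m1) / cd
        disc = c1 * c1 - 4.0 * c0
        sq = np.sqrt(np.maximum(disc, 0.0))
        z0 = 0.5 * (-c1 - sq)
        z1 = 0.5 * (-c1 + sq)
        p0 = (z1 - m1) / (z1 - z0)
    bad = degenerate | (cd <= 0) | (disc < 0) | (z1 == z0) | ~np.isfinite(p0)
    cum = np.cumsum(p, axis=2)
    t = np.argmax(cum > p0[:, :, None], axis=2).astype(np.int64)
    none_above = ~(cum > p0[:, :, None]).any(axis=2)
    t[none_above | bad] = n_bins - 1
    return t


def local_threshold(
    img: Image,
    method: Literal["moments", "isodata"] = "moments",
    radius: int = 15,
    n_bins: int = N_BINS,
    min_contrast: float = 0.0,
) -> np.ndarray:
    """Local auto-threshold; returns a boolean foreground mask.

    For each pixel, the histogram of the (2r+1)-square window centred
    on it (reflect padding) is quantised to ``n_bins`` grey levels over
    the image's global range, a threshold bin T is computed with the
    selected rule, and the pixel is foreground iff its own bin index
    is strictly greater than T.  Constant windows are background;
    ``min_contrast`` extends this degenerate-window rule to noisy
    images: windows whose intensity range is below that fraction of
    the global range are also background (both histogram rules would
    otherwise split pure background noise).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if method not in ("moments", "isodata"):
        raise ValueError(f"unknown threshold method {method!r}")
    bins = _quantise(img.pixels, n_bins)
    hist = _local_histograms(bins, radius, n_bins)
    if method == "isodata":
        t = _isodata_thresholds(hist)
    else:
        t = _moments_thresholds(hist)
    fg = bins > t
    if min_contrast > 0:
        occ = hist > 0
        lo = np.argmax(occ, axis=2)
        hi = n_bins - 1 - np.argmax(occ[:, :, ::-1], axis=2)
        fg &= (hi - lo) >= min_contrast * (n_bins - 1)
    return fg


def preprocess(img: Image, cfg: PreprocessConfig | None = None) -> Image:
    """Full preprocessing chain up to (but excluding) thresholding.

    Order: gamma -> despeckle -> remove outliers -> attribute top-hat.
    """
    cfg = cfg or PreprocessConfig()
    out = adjust_gamma(img, cfg.gamma)
    out = despeckle(out)
    out = remove_outliers(
        out, radius=cfg.outlier_radius, threshold=cfg.outlier_threshold / 255.0
    )
    out = attribute_tophat(out, cfg.tophat_area_lambda)
    return out


def segment(img: Image, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Preprocess and threshold; returns the binary cell-body mask.

    The raw threshold output is cleaned up with hole filling (windows
    fully inside a large bright body are degenerate and threshold to
    background) and a 3x3 binary opening (removes 1-px process stubs
    and speckle).  Artefact pixels (``analysed_mask`` False) are
    forced to background.
    """
    cfg = cfg or PreprocessConfig()
    pre = preprocess(img, cfg)
    binary = local_threshold(
        pre,
        cfg.threshold_method,
        cfg.threshold_radius,
        min_contrast=cfg.threshold_min_contrast,
    )
    binary = ndimage.binary_fill_holes(binary)
    binary = ndimage.binary_opening(
        binary, structure=ndimage.generate_binary_structure(2, 1)
    )
    return binary & img.analysed_mask
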