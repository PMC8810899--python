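"""Image and configuration I/O.

Single-channel TIFF and PNG readers normalising 8/16-bit data to the
internal unit-interval float representation; 8-bit mask writers; YAML
configuration mirroring :class:`~retimorph.imaging_core.PreprocessConfig`.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .imaging_core import DEFAULT_SCALE_UM_PER_PX, Image, PreprocessConfig


def _normalise(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:  # collapse RGB(A) to luminance of the first channels
        arr = arr[..., :3].mean(axis=2)
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(float) / info.max
    arr = arr.astype(float)
    return arr / arr.max() if arr.max() > 1.0 else arr


def read_image(path: str | Path, scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX) -> Image:
    """Read a TIFF/PNG into a unit-interval grayscale :class:`Image`."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return Image(_normalise(arr), scale_um_per_px)


def read_mask(path: str | Path) -> np.ndarray:
    """Read an 8-bit 0/255 mask image into a boolean grid."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return np.asarray(arr) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean grid as an 8-bit 0/255 TIFF (or PNG by suffix)."""
    path = Path(path)
    data = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_image(path: str | Path, img: Image | np.ndarray) -> None:
    """Write float unit-interval pixels as 16-bit TIFF / 8-bit PNG."""
    path = Path(path)
    pixels = img.pixels if isinstance(img, Image) else np.asarray(img)
    if pixels.ndim == 3:  # RGB overlay, already uint8
        iio.imwrite(path, pixels.astype(np.uint8))
        return
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (np.clip(pixels, 0, 1) * 65535).astype(np.uint16))
    else:
        iio.imwrite(path, (np.clip(pixels, 0, 1) * 255).astype(np.uint8))


def load_config(path: str | Path | None) -> PreprocessConfig:
    """Load a PreprocessConfig from YAML; None yields the defaults."""
    if path is None:
        return PreprocessConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PreprocessConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PreprocessConfig(**data)


def save_config(cfg: PreprocessConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))
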