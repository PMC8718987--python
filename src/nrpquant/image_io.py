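"""Raster I/O and the canonical reductive-intensity representation.

A digitized NRP membrane is a grayscale photograph in which MnO2 deposit is
*dark*. All quantification in this package runs on the inverted "reductive
scale", where larger pixel values mean more deposit, i.e. more reductive
capacity in the applied sample. This module reads 8/16-bit TIFF and PNG
files, normalizes them to floating point [0, 1], and performs the
grayscale inversion exactly once (double inversion is a guarded error).

Conventions (used everywhere in the package):

* working pixel scale is float64 in [0, 1]; integer code spaces exist only
  at file boundaries;
* images are indexed (row, column), 0-based, origin at the top-left;
  dorsoventral profiles run along increasing row index;
* RGB collapses to luminance with ITU-R BT.601 weights 0.299/0.587/0.114.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import DimensionError, FormatError, StateError

__all__ = ["MembraneImage", "load_image", "to_reductive_scale", "save_image"]

#: ITU-R BT.601 luminance weights for RGB collapse.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class MembraneImage:
    """A 2D reductive-intensity field derived from a digitized membrane.

    Parameters
    ----------
    pixels
        2D float array. Values are dimensionless in [0, 1].
    scale_note
        Free-text provenance (source file, original bit depth, transforms).
    is_reductive_scale
        True once the image has been inverted so that larger values mean
        darker membrane, i.e. more MnO2 deposit.
    """

    pixels: np.ndarray
    scale_note: str = ""
    is_reductive_scale: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise DimensionError(f"expected a non-empty 2D pixel grid, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise DimensionError("pixel values must be finite")
        if px.min() < 0.0 or px.max() > 1.0:
            raise DimensionError("pixel values must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray, note: str = "") -> "MembraneImage":
        """Return a copy with new pixels and an appended scale note."""
        scale_note = self.scale_note + (("; " + note) if note else "")
        return replace(self, pixels=pixels, scale_note=scale_note)


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[:, :, :3].astype(np.float64)
        w = np.asarray(LUMA_WEIGHTS)
        return rgb @ w
    raise FormatError(f"unsupported image layout with shape {arr.shape}")


def load_image(path: str | os.PathLike) -> MembraneImage:
    """Read a TIFF/PNG membrane scan as raw luminance normalized to [0, 1].

    The result has ``is_reductive_scale=False``: bright pixels are still
    bright. Apply :func:`to_reductive_scale` before quantification.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises various backend errors
        raise FormatError(f"cannot read image {path!r}: {exc}") from exc
    if arr.size == 0:
        raise DimensionError(f"zero-sized image: {path}")

    if arr.dtype == np.uint8:
        full_scale, depth = 255.0, 8
    elif arr.dtype == np.uint16:
        full_scale, depth = 65535.0, 16
    elif np.issubdtype(arr.dtype, np.floating):
        full_scale, depth = 1.0, 0
    else:
        raise FormatError(f"unsupported bit depth {arr.dtype} in {path}")

    lum = _to_luminance(np.asarray(arr, dtype=np.float64)) / full_scale
    lum = np.clip(lum, 0.0, 1.0)
    note = f"loaded {os.path.basename(path)} ({depth or 'float'}-bit)"
    return MembraneImage(pixels=lum, scale_note=note, is_reductive_scale=False)


def to_reductive_scale(img: MembraneImage) -> MembraneImage:
    """Invert a luminance image so pixel intensity represents reductive capacity.

    Every pixel v becomes 1 - v. Raises :class:`StateError` if the image is
    already on the reductive scale, preventing a silent double inversion.
    """
    if img.is_reductive_scale:
        raise StateError("image is already on the reductive scale")
    out = img.with_pixels(1.0 - img.pixels, note="inverted to reductive scale")
    return replace(out, is_reductive_scale=True)


def save_image(img: MembraneImage, path: str | os.PathLike, bit_depth: int = 16) -> str:
    """Quantize to the requested bit depth and write TIFF or PNG (by extension).

    Round trip guarantee: ``load_image(save_image(img, p))`` matches ``img``
    within one quantization step of the chosen depth (the scale flag is not
    stored in the file; the caller re-asserts it).
    """
    if bit_depth not in (8, 16):
        raise FormatError(f"bit_depth must be 8 or 16, got {bit_depth}")
    path = os.fspath(path)
    if not path:
        raise OSError("empty output path")
    full_scale = 255 if bit_depth == 8 else 65535
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    codes = np.rint(img.pixels * full_scale).astype(dtype)
    ext = os.path.splitext(path)[1].lower()
    try:
        if ext in (".tif", ".tiff"):
            tifffile.imwrite(path, codes)
        elif ext == ".png":
            iio.imwrite(path, codes)
        else:
            raise FormatError(f"unsupported output extension {ext!r} (use .tif/.tiff/.png)")
    except FormatError:
        raise
    except Exception as exc:
        raise OSError(f"cannot write image {path!r}: {exc}") from exc
    return path
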