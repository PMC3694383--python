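"""Grayscale image and label-map containers plus PNG/TIFF I/O.

All downstream statistics assume integer gray levels in ``[0, L-1]``; the
containers here enforce that invariant once so the math never has to.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "LabelMap",
    "read_gray_image",
    "read_label_map",
    "quantize",
    "write_image",
]


@dataclass
class GrayImage:
    """A 2-D grid of integer intensities together with its gray-level count L.

    Parameters
    ----------
    pixels : ndarray of int, shape (height, width)
        Intensities; every value must lie in ``[0, levels - 1]``.
    levels : int, default 256
        Number of discrete gray levels L (256 for 8-bit images).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("pixels must hold integer gray levels")
            arr = arr.astype(np.int64)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if arr.min() < 0 or arr.max() >= self.levels:
            raise ValueError(
                f"intensities must lie in [0, {self.levels - 1}]; "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "pixels", arr.astype(np.int64, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMap:
    """Per-pixel integer class identifiers paired with a GrayImage."""

    labels: np.ndarray
    classes: tuple = field(default=None)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("labels must be a non-empty 2-D array")
        arr = arr.astype(np.int64, copy=False)
        if self.classes is None:
            object.__setattr__(self, "classes", tuple(np.unique(arr).tolist()))
        else:
            object.__setattr__(self, "classes", tuple(self.classes))
            extra = set(np.unique(arr).tolist()) - set(self.classes)
            if extra:
                raise ValueError(f"labels contain values outside classes: {sorted(extra)}")
        object.__setattr__(self, "labels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def quantize(img: GrayImage, target_levels: int) -> GrayImage:
    """Requantize an image to ``target_levels`` gray levels.

    Equal-width binning over the observed intensity range,
    ``floor((v - vmin) * L_out / (vmax - vmin + 1))``, which reduces to
    ``floor(v * L_out / L_in)`` when the input spans its full grid.  A
    constant image maps to all zeros (the range is degenerate and any
    constant would do).  When the observed span is narrower than the target
    grid, an affine stretch ``round((v - vmin)(L_out - 1)/(vmax - vmin))``
    is used instead so both extremes are attained.
    """
    if target_levels < 2:
        raise ValueError("target_levels must be >= 2")
    v = img.pixels
    vmin, vmax = int(v.min()), int(v.max())
    span = vmax - vmin + 1
    if span == 1:
        out = np.zeros_like(v)
    elif span >= target_levels:
        out = (v - vmin) * target_levels // span
    else:
        out = np.floor((v - vmin) * (target_levels - 1) / (vmax - vmin) + 0.5).astype(np.int64)
    return GrayImage(out, levels=target_levels)


def _collapse_channels(arr: np.ndarray, path: os.PathLike | str) -> np.ndarray:
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop a fully opaque alpha channel
            alpha = arr[:, :, 3]
            if np.all(alpha == alpha.flat[0]):
                arr = arr[:, :, :3]
        if arr.ndim == 3 and np.all(arr == arr[:, :, :1]):
            return arr[:, :, 0]
    raise ValueError(f"{path}: multi-channel image cannot be collapsed losslessly to grayscale")


def read_gray_image(path: os.PathLike | str, levels: int = 256) -> GrayImage:
    """Read a single-channel PNG/TIFF file as a :class:`GrayImage` with L = ``levels``.

    16-bit (or otherwise deeper) samples are requantized with :func:`quantize`
    so that the maximum observed sample maps to ``levels - 1``.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise OSError(f"could not read image {path}: {exc}") from exc
    arr = _collapse_channels(np.asarray(arr), path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path}: expected integer samples, got {arr.dtype}")
    arr = arr.astype(np.int64)
    if arr.max() < levels:
        return GrayImage(arr, levels=levels)
    img = GrayImage(arr, levels=int(arr.max()) + 1)
    return quantize(img, levels)


def read_label_map(path: os.PathLike | str) -> LabelMap:
    arr = _collapse_channels(np.asarray(iio.imread(path)), path)
    return LabelMap(arr.astype(np.int64))


def write_image(img, path: os.PathLike | str) -> None:
    """Write a GrayImage or LabelMap to PNG/TIFF (8-bit when L <= 256)."""
    if isinstance(img, GrayImage):
        arr = img.pixels
        if img.levels <= 256:
            out = arr.astype(np.uint8)
        else:
            out = arr.astype(np.uint16)
    elif isinstance(img, LabelMap):
        if img.labels.min() < 0 or img.labels.max() > 255:
            raise ValueError("label values must fit in [0, 255] for export")
        out = img.labels.astype(np.uint8)
    else:
        raise TypeError(f"cannot write object of type {type(img).__name__}")
    iio.imwrite(path, out)
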