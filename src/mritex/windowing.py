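"""Recognition-window enumeration and pyramid subsampling.

An image is browsed by a fixed-size recognition window (RW), row-major
(top-to-down, left-to-right), non-overlapping by default.  Overlap is
expressed as a stride smaller than the window size.  Partial windows at the
right/bottom margins are discarded so every window holds exactly
``height * width`` pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image_io import GrayImage

__all__ = ["WindowSpec", "Window", "window_grid_shape", "enumerate_windows",
           "build_pyramid_level", "pyramid"]


@dataclass(frozen=True)
class WindowSpec:
    """Shape and scanning stride of the recognition window (default 6x6)."""

    height: int = 6
    width: int = 6
    stride_rows: int | None = None
    stride_cols: int | None = None

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("window size must be >= 1")
        if self.stride_rows is None:
            object.__setattr__(self, "stride_rows", self.height)
        if self.stride_cols is None:
            object.__setattr__(self, "stride_cols", self.width)
        if self.stride_rows < 1 or self.stride_cols < 1:
            raise ValueError("strides must be >= 1")

    @property
    def overlapping(self) -> bool:
        return self.stride_rows < self.height or self.stride_cols < self.width

    @property
    def n_pixels(self) -> int:
        return self.height * self.width


@dataclass(frozen=True)
class Window:
    """One RW placement: top-left origin and the pixel block it covers."""

    row: int
    col: int
    block: np.ndarray  # shape (spec.height, spec.width), view into the source

    @property
    def origin(self) -> tuple[int, int]:
        return (self.row, self.col)


def window_grid_shape(img_height: int, img_width: int, spec: WindowSpec) -> tuple[int, int]:
    """Number of (rows, cols) of window placements; 0 when the window does not fit."""
    if img_height < spec.height or img_width < spec.width:
        warnings.warn("window larger than image: empty window grid", stacklevel=2)
        return (0, 0)
    rows = (img_height - spec.height) // spec.stride_rows + 1
    cols = (img_width - spec.width) // spec.stride_cols + 1
    return (rows, cols)


def enumerate_windows(img: GrayImage, spec: WindowSpec) -> list[Window]:
    """All window placements in row-major order (deterministic)."""
    rows, cols = window_grid_shape(img.height, img.width, spec)
    px = img.pixels
    out: list[Window] = []
    for r in range(rows):
        r0 = r * spec.stride_rows
        for c in range(cols):
            c0 = c * spec.stride_cols
            out.append(Window(r0, c0, px[r0:r0 + spec.height, c0:c0 + spec.width]))
    return out


def window_blocks(img: GrayImage, spec: WindowSpec) -> np.ndarray:
    """All window pixel blocks as one array of shape (rows, cols, h, w) (views)."""
    rows, cols = window_grid_shape(img.height, img.width, spec)
    if rows == 0 or cols == 0:
        return np.empty((rows, cols, spec.height, spec.width), dtype=img.pixels.dtype)
    sw = sliding_window_view(img.pixels, (spec.height, spec.width))
    return sw[::spec.stride_rows, ::spec.stride_cols][:rows, :cols]


def build_pyramid_level(img: GrayImage) -> GrayImage:
    """One subsampling step: 2x2 block means, rounded half-up; L unchanged.

    Output is ``(h // 2, w // 2)``; a trailing odd row/column is dropped.
    """
    h, w = img.shape
    if h < 2 or w < 2:
        raise ValueError("image must be at least 2x2 to build a pyramid level")
    h2, w2 = h // 2, w // 2
    blocks = img.pixels[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2)
    mean = blocks.mean(axis=(1, 3))
    return GrayImage(np.floor(mean + 0.5).astype(np.int64), levels=img.levels)


def pyramid(img: GrayImage, levels: int = 2) -> list[GrayImage]:
    """Pyramid [L0, L1, ...] with ``levels`` tiers; L0 is the source itself."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = [img]
    for _ in range(levels - 1):
        out.append(build_pyramid_level(out[-1]))
    return out
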