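"""Feature maps and feature spaces: one operator value per recognition window.

Browsing an image with the RW turns it into a subsampled map (e.g. a 48x48
image under a non-overlapping 6x6 RW becomes an 8x8 map).  Maps are kept as
real numbers internally; quantization to integer gray levels happens only on
export via :func:`scale_to_levels`, because the interval model downstream
needs full numeric resolution.

The engine shares work aggressively: all second-order operators with the
same ring radius d reuse one pass that gathers, per window, the ordered
(center, partner) gray-level pairs (partners looked up in the full image so
the window's context contributes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .cooccurrence import ring_offsets
from .image_io import GrayImage
from .second_order import OperatorSpec
from .windowing import WindowSpec, pyramid, window_blocks, window_grid_shape

__all__ = ["FeatureMap", "FeatureSpace", "compute_feature_map",
           "compute_feature_maps", "scale_to_levels", "build_feature_space",
           "TextureFeatureExtractor"]


@dataclass
class FeatureMap:
    """Operator outputs on the window grid of one image at one pyramid level."""

    op: OperatorSpec
    values: np.ndarray  # (rows, cols) float
    source_shape: tuple[int, int]
    level: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("feature map values must be finite")
        object.__setattr__(self, "values", v)


@dataclass
class FeatureSpace:
    """Feature maps for a set of images, indexed by (image_id, op_index, level)."""

    maps: dict
    ops: list
    window: WindowSpec
    levels: int
    image_ids: list

    def map_for(self, image_id, op_index: int, level: int) -> FeatureMap:
        return self.maps[(image_id, op_index, level)]

    def to_frame(self):
        """Long-format DataFrame: image, level, operator, row, col, value."""
        import pandas as pd

        rows = []
        for (img_id, oi, lvl), fm in sorted(self.maps.items(),
                                            key=lambda kv: (str(kv[0][0]), kv[0][1], kv[0][2])):
            r, c = np.indices(fm.values.shape)
            rows.append(pd.DataFrame({
                "image": img_id, "level": lvl, "operator": self.ops[oi].label,
                "row": r.ravel(), "col": c.ravel(), "value": fm.values.ravel(),
            }))
        return pd.concat(rows, ignore_index=True)


def _pair_codes(img: GrayImage, spec: WindowSpec, d: int) -> np.ndarray:
    """Per-window ordered pair codes i*L + j, shape (rows, cols, 8d * h * w).

    Entries are -1 where the ring partner falls outside the image.
    """
    L = img.levels
    px = img.pixels
    H, W = px.shape
    offs = ring_offsets(d).offsets
    K = len(offs)
    codes = np.full((H, W, K), -1, dtype=np.int64)
    for k, (dr, dc) in enumerate(offs):
        ra, rb = max(0, -dr), min(H, H - dr)
        ca, cb = max(0, -dc), min(W, W - dc)
        if ra >= rb or ca >= cb:
            continue
        codes[ra:rb, ca:cb, k] = (px[ra:rb, ca:cb] * L
                                  + px[ra + dr:rb + dr, ca + dc:cb + dc])
    rows, cols = window_grid_shape(H, W, spec)
    sw = sliding_window_view(codes, (spec.height, spec.width), axis=(0, 1))
    sw = sw[::spec.stride_rows, ::spec.stride_cols][:rows, :cols]
    return sw.reshape(rows, cols, -1)


def _second_order_value(op: OperatorSpec, i: np.ndarray, j: np.ndarray,
                        p: np.ndarray, L: int) -> float:
    """Operator value from the sparse cells (i, j, p) of one window's matrix."""
    ps = op.params
    name = op.name
    if name == "HG":
        return float(np.sum(p ** ps["n3"]))
    adiff = np.abs(i - j)
    if name == "CT":
        return float(np.sum(adiff ** ps["n4"] * p ** ps["n5"]))
    if name == "ID":
        return float(np.sum(p ** ps["n6"] / (1.0 + adiff ** ps["n7"])))
    if name == "ET":
        logs = np.log(p) / math.log(ps["k1"])
        return float(-np.sum(p ** ps["n8"] * logs ** ps["n9"]))
    if name == "CR":
        mu_x = float(np.sum(i * p))
        mu_y = float(np.sum(j * p))
        sigma = math.sqrt(float(np.sum((i - mu_x) ** 2 * p))) * \
            math.sqrt(float(np.sum((j - mu_y) ** 2 * p)))
        if sigma == 0.0:
            return 0.0
        second = (i - mu_y) if op.variant == "as_printed" else (j - mu_y)
        return float(np.sum((i - mu_x) * second * p ** ps["n10"]) / sigma ** ps["n11"])
    # DE
    pd = np.bincount(adiff.astype(np.int64), weights=p ** ps["q"], minlength=L)
    pd = pd[pd > 0]
    logs = np.log(pd) / math.log(ps["k2"])
    return float(-np.sum(pd ** ps["n12"] * logs ** ps["n13"]))


def compute_feature_maps(img: GrayImage, ops: list, spec: WindowSpec,
                         level: int = 0) -> list:
    """Feature maps for several operators in one pass (shared per-d work)."""
    rows, cols = window_grid_shape(img.height, img.width, spec)
    if rows == 0 or cols == 0:
        raise ValueError("window larger than image: degenerate window grid")
    out = [np.empty((rows, cols)) for _ in ops]
    L = img.levels

    first = [(oi, op) for oi, op in enumerate(ops) if not op.is_second_order]
    if first:
        blocks = window_blocks(img, spec).reshape(rows, cols, -1).astype(float)
        mean = blocks.mean(axis=-1)
        for oi, op in first:
            if op.name == "M":
                n1 = op.params["n1"]
                out[oi][:] = mean if n1 == 1 else (blocks ** n1).mean(axis=-1)
            else:
                out[oi][:] = ((blocks - mean[..., None]) ** op.params["n2"]).mean(axis=-1)

    by_d: dict[int, list] = {}
    for oi, op in enumerate(ops):
        if op.is_second_order:
            by_d.setdefault(op.d, []).append((oi, op))
    for d, group in sorted(by_d.items()):
        codes = _pair_codes(img, spec, d)
        for r in range(rows):
            for c in range(cols):
                win = codes[r, c]
                win = win[win >= 0]
                if win.size == 0:
                    raise ValueError("degenerate co-occurrence matrix: no realized pairs")
                u, cnt = np.unique(win, return_counts=True)
                p = cnt / win.size
                i = (u // L).astype(float)
                j = (u - (u // L) * L).astype(float)
                for oi, op in group:
                    out[oi][r, c] = _second_order_value(op, i, j, p, L)
        del codes
    return [FeatureMap(op, vals, img.shape, level) for op, vals in zip(ops, out)]


def compute_feature_map(img: GrayImage, op: OperatorSpec,
                        spec: WindowSpec) -> FeatureMap:
    """Feature map of a single operator (one value per RW, row-major grid)."""
    return compute_feature_maps(img, [op], spec)[0]


def scale_to_levels(fm: FeatureMap, L: int = 256) -> GrayImage:
    """Linear min-max rescale of a map to integer gray levels [0, L-1].

    Rounding is half-up; a constant map becomes all zeros.
    """
    v = fm.values
    lo, hi = v.min(), v.max()
    if hi == lo:
        return GrayImage(np.zeros(v.shape, dtype=np.int64), levels=L)
    scaled = (v - lo) / (hi - lo) * (L - 1)
    return GrayImage(np.floor(scaled + 0.5).astype(np.int64), levels=L)


def build_feature_space(imgs: list, ops: list, spec: WindowSpec,
                        levels: int = 2, image_ids: list | None = None) -> FeatureSpace:
    """One FeatureMap per (image, operator, pyramid level), deterministic order."""
    if not imgs:
        raise ValueError("need at least one image")
    if not ops:
        raise ValueError("need at least one operator")
    if image_ids is None:
        image_ids = list(range(len(imgs)))
    maps = {}
    for img_id, img in zip(image_ids, imgs):
        for lvl, level_img in enumerate(pyramid(img, levels)):
            try:
                fms = compute_feature_maps(level_img, ops, spec, level=lvl)
            except ValueError as exc:
                raise ValueError(f"image {img_id!r}, level {lvl}: {exc}") from exc
            for oi, fm in enumerate(fms):
                maps[(img_id, oi, lvl)] = fm
    return FeatureSpace(maps, list(ops), spec, levels, list(image_ids))


class TextureFeatureExtractor(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer from grayscale images to feature spaces.

    Parameters
    ----------
    ops : list of OperatorSpec or str, default "brain"
        Operators to apply, or a body-region preset name
        (brain/heart/liver/bone) resolved to its default parameter set.
    window : int or (int, int), default 6
        Recognition-window size.
    stride : int or (int, int), optional
        Scanning stride; defaults to the window size (no overlap).
    levels : int, default 2
        Number of pyramid levels (L0 = native resolution).
    """

    def __init__(self, ops="brain", window=6, stride=None, levels=2):
        self.ops = ops
        self.window = window
        self.stride = stride
        self.levels = levels

    def _resolved(self):
        from .presets import default_ops

        ops = default_ops(self.ops) if isinstance(self.ops, str) else list(self.ops)
        wh, ww = (self.window, self.window) if np.isscalar(self.window) else self.window
        if self.stride is None:
            sr = sc = None
        else:
            sr, sc = (self.stride, self.stride) if np.isscalar(self.stride) else self.stride
        return ops, WindowSpec(wh, ww, sr, sc)

    def fit(self, X=None, y=None):
        self.ops_, self.window_ = self._resolved()
        return self

    def transform(self, X) -> FeatureSpace:
        """Compute the feature space of a GrayImage or a list of them."""
        if not hasattr(self, "ops_"):
            self.fit()
        imgs = [X] if isinstance(X, GrayImage) else list(X)
        return build_feature_space(imgs, self.ops_, self.window_, self.levels)
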