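"""All-directions co-occurrence matrix built on a discrete-circumference ring.

Classic Haralick co-occurrence matrices accumulate gray-level pairs along
four fixed directions (0, 45, 90, 135 degrees).  Here, instead, every pixel
of the recognition window is treated as the center of a discrete
circumference of radius ``d`` and pairs with *every* pixel on that ring, so
all directions contribute at once.  The ring is the Chebyshev square ring
(all displacements with max(|dr|, |dc|) = d), which has exactly ``8 d``
points at every radius — 16 at d=2, matching the count the classic d=2
example yields (a 3x3 window then contributes 9 * 16 = 144 increments).

Ring partners are looked up in the *full image*, not just the window, so the
matrix also captures contextual information around the window; partners that
fall outside the image are skipped and the matrix is renormalized over the
realized pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage
from .windowing import Window

__all__ = ["RingOffsets", "CooccurrenceMatrix", "CooccurrenceMarginals",
           "ring_offsets", "cooccurrence_matrix", "marginals"]


@dataclass(frozen=True)
class RingOffsets:
    """The displacement set of the discrete circumference at radius ``d``."""

    d: int
    offsets: tuple  # of (drow, dcol) pairs, clockwise from (-d, -d)


def ring_offsets(d: int) -> RingOffsets:
    """The 8d (drow, dcol) displacements at Chebyshev distance ``d``.

    Deterministic clockwise order starting from the top-left corner
    ``(-d, -d)``:  top edge left-to-right, right edge downward, bottom edge
    right-to-left, left edge upward.
    """
    if d < 1:
        raise ValueError("ring radius d must be >= 1")
    top = [(-d, c) for c in range(-d, d + 1)]
    right = [(r, d) for r in range(-d + 1, d + 1)]
    bottom = [(d, c) for c in range(d - 1, -d - 1, -1)]
    left = [(r, -d) for r in range(d - 1, -d, -1)]
    offsets = tuple(top + right + bottom + left)
    assert len(offsets) == 8 * d
    return RingOffsets(d, offsets)


@dataclass
class CooccurrenceMatrix:
    """L x L pair-count matrix and its joint probability normalization."""

    d: int
    levels: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.levels, self.levels):
            raise ValueError("counts must be an L x L matrix")
        if c.min() < 0:
            raise ValueError("counts must be non-negative")
        if c.sum() == 0:
            raise ValueError("degenerate co-occurrence matrix: no realized pairs")
        object.__setattr__(self, "counts", c.astype(np.int64, copy=False))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def p(self) -> np.ndarray:
        """Joint probabilities p_d(i, j); sums to 1."""
        return self.counts / self.total


@dataclass(frozen=True)
class CooccurrenceMarginals:
    """Marginal statistics of a co-occurrence matrix.

    ``mu_x``/``sigma_x`` describe the first pair member (the ring center),
    ``mu_y``/``sigma_y`` the second (the ring partner); ``p_diff[k]`` is the
    gray-level-difference distribution sum_{|i-j|=k} p_d(i,j)^q.
    """

    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_diff: np.ndarray
    q: int = 1


def cooccurrence_matrix(img: GrayImage, window: Window, d: int) -> CooccurrenceMatrix:
    """Build the ring co-occurrence matrix for one recognition window.

    Every window pixel is a ring center; each (center, partner) ordered pair
    whose partner lies inside the image increments
    ``counts[value(center), value(partner)]``.  For a fully interior window
    the total is exactly ``n_pixels * 8 d``.
    """
    if d < 1:
        raise ValueError("ring radius d must be >= 1")
    L = img.levels
    px = img.pixels
    H, W = px.shape
    na, nb = window.block.shape
    r0, c0 = window.row, window.col
    counts = np.zeros((L, L), dtype=np.int64)
    for dr, dc in ring_offsets(d).offsets:
        # valid sub-rectangle of window centers whose partner stays in-image
        ra = max(r0, -dr)
        rb = min(r0 + na, H - dr)
        ca = max(c0, -dc)
        cb = min(c0 + nb, W - dc)
        if ra >= rb or ca >= cb:
            continue
        ci = px[ra:rb, ca:cb].ravel()
        cj = px[ra + dr:rb + dr, ca + dc:cb + dc].ravel()
        np.add.at(counts, (ci, cj), 1)
    return CooccurrenceMatrix(d, L, counts)


def marginals(cm: CooccurrenceMatrix, q: int = 1) -> CooccurrenceMarginals:
    """Mean/standard-deviation marginals and the difference distribution.

    ``sigma_x``/``sigma_y`` are standard deviations (square roots of the
    probability-weighted squared deviations).  ``q`` exponentiates each cell
    before the difference sums; at q=1 ``p_diff`` sums to 1.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    p = cm.p
    L = cm.levels
    i = np.arange(L, dtype=float)
    px_m = p.sum(axis=1)  # marginal over the first index
    py_m = p.sum(axis=0)
    mu_x = float(i @ px_m)
    mu_y = float(i @ py_m)
    sigma_x = float(np.sqrt((i - mu_x) ** 2 @ px_m))
    sigma_y = float(np.sqrt((i - mu_y) ** 2 @ py_m))
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    k = np.abs(ii - jj).ravel()
    p_diff = np.bincount(k, weights=(p ** q).ravel(), minlength=L)[:L]
    return CooccurrenceMarginals(mu_x, mu_y, sigma_x, sigma_y, p_diff, q)
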