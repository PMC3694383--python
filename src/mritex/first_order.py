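"""First-order statistics: window gray-level histogram and generalized moments.

The N-order moment M(n1) = sum_i i^n1 p(i) and N-order central moment
C(n2) = sum_i (i - M1)^n2 p(i) are functions of the histogram alone and are
blind to spatial arrangement; they mainly separate background (very low M,
low C) from informative tissue (high M, very high C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .windowing import Window

__all__ = ["GrayHistogram", "gray_histogram", "moment", "central_moment"]


@dataclass(frozen=True)
class GrayHistogram:
    """Probability p(i) of each gray level i in [0, L-1] within one window."""

    p: np.ndarray
    levels: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.shape[0] != self.levels:
            raise ValueError("p must be a 1-D array of length levels")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("histogram must sum to 1")
        object.__setattr__(self, "p", p)


def gray_histogram(window: Window | np.ndarray, levels: int) -> GrayHistogram:
    """Normalized gray-level histogram of a window's pixel block."""
    block = window.block if isinstance(window, Window) else np.asarray(window)
    if block.size == 0:
        raise ValueError("empty window")
    if block.min() < 0 or block.max() >= levels:
        raise ValueError(f"window intensities must lie in [0, {levels - 1}]")
    counts = np.bincount(block.ravel().astype(np.int64), minlength=levels)
    return GrayHistogram(counts / block.size, levels)


def moment(h: GrayHistogram, n1: int) -> float:
    """Generalized N-order moment M(n1); n1=1 is the window mean."""
    if n1 < 0:
        raise ValueError("n1 must be a natural number")
    i = np.arange(h.levels, dtype=float)
    return float(np.sum(i ** n1 * h.p))


def central_moment(h: GrayHistogram, n2: int, *, center_order: int | None = None) -> float:
    """Generalized N-order central moment C(n2).

    Centering uses the first-order mean M(1) by default.  ``center_order``
    switches to centering on the raw moment M(center_order) for fidelity
    experiments with the literal printed form.
    """
    if n2 < 0:
        raise ValueError("n2 must be a natural number")
    center = moment(h, 1 if center_order is None else center_order)
    i = np.arange(h.levels, dtype=float)
    return float(np.sum((i - center) ** n2 * h.p))
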