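"""Seeded synthetic phantoms with per-pixel ground truth.

The phantoms emulate the gross structure the texture operators assume in a
transversal grayscale scan: a low-intensity noisy background, one or more
textured "tissue" regions, and a bright boundary band (a skull-like
annulus).  They carry exact label maps, so every stage — operators, feature
maps, interval model, segmentation scoring — is testable without any
clinical data.  All randomness flows from the single spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import GrayImage, LabelMap

__all__ = ["TexturePatchSpec", "RegionSpec", "PhantomSpec",
           "make_texture_patch", "make_phantom", "brainlike_spec"]

_KINDS = ("constant", "uniform_noise", "gaussian_noise", "checkerboard",
          "stripes", "blob_process")


@dataclass(frozen=True)
class TexturePatchSpec:
    """Recipe for one texture: kind plus its mean/amplitude/period parameters.

    ``mean`` is the target gray level; ``amplitude`` the half-range of the
    periodic or uniform kinds; ``sigma`` the Gaussian noise scale;
    ``period`` and ``orientation`` shape the periodic kinds; blob_process
    scatters ``density``-many Gaussian bumps per 1000 pixels of width
    ``period``.  Intensities are clipped to [0, L-1].
    """

    kind: str
    mean: float = 128.0
    amplitude: float = 0.0
    sigma: float = 0.0
    period: int = 2
    orientation: str = "horizontal"
    density: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown texture kind {self.kind!r}")
        if self.period < 1:
            raise ValueError("period must be >= 1")


@dataclass(frozen=True)
class RegionSpec:
    """A geometric region painted with one texture and one class label."""

    shape: str  # 'disk' | 'annulus' | 'rectangle'
    geometry: tuple
    texture: TexturePatchSpec
    label: int

    def __post_init__(self) -> None:
        if self.shape not in ("disk", "annulus", "rectangle"):
            raise ValueError(f"unknown region shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Frame size, background texture, ordered regions, and the master seed.

    Regions are painted in order; later regions overwrite earlier ones, and
    each boundary pixel takes the topmost region's label (no mixed classes).
    """

    height: int = 96
    width: int = 96
    levels: int = 256
    background: TexturePatchSpec = field(
        default_factory=lambda: TexturePatchSpec("gaussian_noise", mean=10, sigma=5))
    background_label: int = 0
    regions: tuple = ()
    seed: int = 0


def make_texture_patch(spec: TexturePatchSpec, h: int, w: int,
                       seed_or_rng=0, levels: int = 256) -> GrayImage:
    """Generate an h x w patch of the requested texture, clipped to [0, L-1]."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    if spec.kind == "constant":
        vals = np.full((h, w), spec.mean)
    elif spec.kind == "uniform_noise":
        vals = rng.uniform(spec.mean - spec.amplitude, spec.mean + spec.amplitude,
                           size=(h, w))
    elif spec.kind == "gaussian_noise":
        vals = spec.mean + rng.normal(0.0, spec.sigma, size=(h, w))
    elif spec.kind == "checkerboard":
        r, c = np.indices((h, w))
        phase = (r // spec.period + c // spec.period) % 2
        vals = spec.mean + spec.amplitude * (2 * phase - 1)
        if spec.sigma:
            vals = vals + rng.normal(0.0, spec.sigma, size=(h, w))
    elif spec.kind == "stripes":
        r, c = np.indices((h, w))
        axis = r if spec.orientation == "horizontal" else c
        phase = (axis // spec.period) % 2
        vals = spec.mean + spec.amplitude * (2 * phase - 1)
        if spec.sigma:
            vals = vals + rng.normal(0.0, spec.sigma, size=(h, w))
    else:  # blob_process
        vals = np.full((h, w), float(spec.mean))
        n_blobs = max(1, int(spec.density * h * w / 1000.0))
        rr = rng.uniform(0, h, n_blobs)
        cc = rng.uniform(0, w, n_blobs)
        amp = rng.uniform(0.5, 1.0, n_blobs) * spec.amplitude
        r, c = np.indices((h, w))
        for br, bc, ba in zip(rr, cc, amp):
            d2 = (r - br) ** 2 + (c - bc) ** 2
            vals += ba * np.exp(-d2 / (2.0 * spec.period ** 2))
        if spec.sigma:
            vals = vals + rng.normal(0.0, spec.sigma, size=(h, w))
    out = np.clip(np.floor(vals + 0.5), 0, levels - 1).astype(np.int64)
    return GrayImage(out, levels=levels)


def _region_mask(region: RegionSpec, h: int, w: int) -> np.ndarray:
    r, c = np.indices((h, w))
    if region.shape == "disk":
        cy, cx, rad = region.geometry
        if rad <= 0 or cy - rad < -0.5 or cy + rad > h - 0.5 or \
                cx - rad < -0.5 or cx + rad > w - 0.5:
            raise ValueError("disk geometry outside the image frame")
        return (r - cy) ** 2 + (c - cx) ** 2 <= rad ** 2
    if region.shape == "annulus":
        cy, cx, r_in, r_out = region.geometry
        if not 0 <= r_in < r_out or cy + r_out > h - 0.5 or cx + r_out > w - 0.5 \
                or cy - r_out < -0.5 or cx - r_out < -0.5:
            raise ValueError("annulus geometry invalid or outside the frame")
        d2 = (r - cy) ** 2 + (c - cx) ** 2
        return (d2 >= r_in ** 2) & (d2 <= r_out ** 2)
    r0, c0, rh, rw = region.geometry
    if r0 < 0 or c0 < 0 or rh < 1 or rw < 1 or r0 + rh > h or c0 + rw > w:
        raise ValueError("rectangle geometry outside the image frame")
    mask = np.zeros((h, w), dtype=bool)
    mask[r0:r0 + rh, c0:c0 + rw] = True
    return mask


def make_phantom(spec: PhantomSpec) -> tuple[GrayImage, LabelMap]:
    """Render a phantom and its exact label map; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w, L = spec.height, spec.width, spec.levels
    img = make_texture_patch(spec.background, h, w, rng, L).pixels.copy()
    labels = np.full((h, w), spec.background_label, dtype=np.int64)
    for region in spec.regions:
        mask = _region_mask(region, h, w)
        patch = make_texture_patch(region.texture, h, w, rng, L).pixels
        img[mask] = patch[mask]
        labels[mask] = region.label
    return GrayImage(img, levels=L), LabelMap(labels)


def brainlike_spec(height: int = 96, width: int = 96, seed: int = 0,
                   levels: int = 256) -> PhantomSpec:
    """The standard brain-like preset: dark noisy background (class 0), a
    textured central tissue disk (class 1, >= 20% of the frame), and a bright
    skull-like annulus (class 2)."""
    s = min(height, width)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    tissue = RegionSpec(
        "disk", (cy, cx, 0.32 * s),
        TexturePatchSpec("gaussian_noise", mean=110, sigma=25), label=1)
    skull = RegionSpec(
        "annulus", (cy, cx, 0.38 * s, 0.45 * s),
        TexturePatchSpec("gaussian_noise", mean=235, sigma=5), label=2)
    return PhantomSpec(height=height, width=width, levels=levels,
                       regions=(tissue, skull), seed=seed)
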