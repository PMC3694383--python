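# Methods

## Scope and model

`mritex` implements a window-based statistical texture analysis for 2-D
grayscale images with integer intensities in [0, L−1] (L = 256 by default,
512×512 typical). The pipeline is: recognition-window browsing → operator
feedbacks → feature maps/pyramid → supervised interval model →
segmentation. Everything is deterministic given its inputs and seeds.

## Recognition windows and pyramid

The RW has fixed size n_a × n_b (default 6×6) and scans top-to-down,
left-to-right. Non-overlapping scanning is the default; overlap is
expressed as a stride smaller than the window. Partial windows at the
right/bottom margins are **discarded**, not padded, so every window holds
exactly n_a·n_b pixels — the histogram normalization assumes this. At
segmentation time those margin pixels receive a reserved margin label (255)
and are excluded from error computation.

Pyramid level L1 is a 2×2 block-mean subsampling (rounded half-up, trailing
odd row/column dropped) of the source, re-analysed with the same RW.
Operators are **not** chained on feature maps: the second-order formulas
assume gray levels of the source domain, so each level re-analyses an
actual image. Default 2 levels (L0, L1).

## First-order operators

For window histogram p(i):

- M(n1) = Σ_i i^{n1} p(i)
- C(n2) = Σ_i (i − M₁)^{n2} p(i)

C centers on the first-order mean M₁ regardless of any higher n1 configured
for M: centering on a higher-order raw moment is dimensionally incoherent.
A `center_order` flag restores the literal center-on-M(n1) behaviour for
fidelity experiments. 0⁰ is taken as 1, so M(0) = 1 exactly.

## The discrete circumference and the co-occurrence matrix

"All directions at radius d" is realized as the Chebyshev square ring
{(Δr, Δc) : max(|Δr|, |Δc|) = d}, which has 8d members at every radius and
reproduces the canonical 16-pairs-at-d=2 count by construction (a Bresenham
circle agrees at d=2 but not at other radii). Offsets are ordered clockwise
from (−d, −d) for determinism.

Every window pixel is a ring center. Pairs are **ordered** (center →
partner) and counted with repetition: a 3×3 window with interior context
contributes exactly 9·8d increments (144 at d=2). Partners are looked up in
the full image so context just outside the window contributes; partners
falling outside the image are skipped and the matrix renormalized over
realized pairs (no padding, no wrap-around). Normalization is joint:
ΣΣ p_d(i,j) = 1. The matrix uses the image's native L by default; rebin
with `quantize` for speed at large L.

## Second-order operators

With p = p_d(i,j), all exponents natural numbers ≥ 1, log bases ≥ 2:

- HG(d)(n3) = Σ p^{n3}
- CT(d)(n4,n5) = Σ |i−j|^{n4} p^{n5}
- ID(d)(n6,n7) = Σ p^{n6} / (1 + |i−j|^{n7})
- ET(d)(n8,n9) = −Σ p^{n8} (log_{k1} p)^{n9}, zero cells contribute 0
- CR(d)(n10,n11) = Σ (i−μx)(i−μy) p^{n10} / (σx σy)^{n11}
- DE(d)(n12,n13) = −Σ_k p_{x−y}(k)^{n12} (log_{k2} p_{x−y}(k))^{n13},
  with p_{x−y}(k) = Σ_{|i−j|=k} p^{q} (q defaults to 1)

Numeric conventions, chosen deliberately:

- **σ are standard deviations** (square roots of the probability-weighted
  squared deviations). This is what makes CR a bounded correlation-like
  quantity (±1 on pure diagonal/anti-diagonal mass at n10 = n11 = 1).
- **ID uses |i−j|** in the denominator. For even n7 this is identical to
  (i−j)^{n7}; for odd n7 the signed form would divide by zero at i−j = −1,
  which cannot be intended, so the magnitude is used and the spec of the
  operator warns when an odd n7 is configured.
- **CR has two variants**: `as_printed` with numerator (i−μx)(i−μy), and
  `haralick` with the conventional (i−μx)(j−μy). They differ on
  anti-correlated mass (+1 vs −1 on a pure anti-diagonal). `as_printed` is
  the default; both are first-class and tested.
- **Entropy signs are literal**: leading minus, exponentiated log, no
  absolute value. With even n9 (n13) the result is therefore non-positive;
  the interval model only compares feedbacks, so the sign convention is
  harmless as long as it is consistent.
- **Degenerate variance** (constant window) makes CR return the sentinel 0
  with a flag rather than raising, so feature maps are total functions —
  background windows are frequently constant.

## Feature maps

Maps hold real numbers internally; integer quantization happens only on
export (`scale_to_levels`: per-map min–max to [0, L−1], half-up rounding,
constant maps → 0). The engine shares work across operators with the same
radius d: per window it gathers the ordered pair codes once and evaluates
all such operators on the sparse cell list.

## Interval model and dependence-weighted voting

Training windows are labelled by the **majority** of their pixels' labels
(ties excluded). For each (class, operator, level) the model stores the
[q, 1−q] quantile interval of feedbacks (default q = 0.01, to resist noise;
q = 0 gives exact min/max and makes training windows self-consistent by
construction).

At classification each (operator, level) whose value lies in a class's
interval votes for that class with weight
`1 + mean dependence to the other matching operators`, dependence read from
the fixed 8×8 operator dependence table (1 = low … 4 = high; M–C, HG–CT,
ID–ET and CR–DE are the strongly joint pairs). Coherent groups of dependent
operators thus outvote isolated accidental matches; a lone match has weight
1. Ties break toward the smaller class id; permuting operator order cannot
change the result.

Pyramid levels vote independently. An L0 window borrows the value of the L1
window containing its down-scaled center; the same operator family across
two levels is treated as strongly dependent (level 4) because the table has
no level axis. This cross-level combination is an interpretation — the
interval model itself does not prescribe one.

## Automated parameter selection

Interactive expert tuning is replaced by a deterministic per-family grid
search over the shipped body-region parameter grids (brain, heart, liver,
bone). Candidates are scored by the summed normalized pairwise interval
overlap across classes and levels (lower = better separation); because the
score is additive over operators the search is separable, and the first
candidate wins ties. It is off by default; the default configurations use
n1 = 1, n2 = 2 (the values that reliably split background from content) and
d = 2 where the grid offers it.

## Synthetic phantoms

The generator emulates the gross layout the operators assume: a dark noisy
background (Gaussian, mean 10, σ 5, class 0), a textured tissue disk
(Gaussian, mean 110, σ 25, radius 0.32·min(H, W) — ≥ 20 % of the frame,
class 1) and a bright skull-like annulus (mean 235, σ 5, radii
0.38–0.45·min(H, W), class 2), all clipped to [0, L−1] and rounded.
Checkerboard, stripe, uniform-noise and Gaussian-blob textures are also
available for targeted fixtures. All randomness flows from the single spec
seed; regions are painted in order and boundary pixels take the topmost
region's label.

What the phantoms do **not** emulate: MR acquisition physics (no T1/T2/PD
contrast mechanisms, bias fields, Rician noise, partial-volume gradients) or
anatomically realistic shapes. Passing the segmentation bound on phantoms
shows the pipeline is internally coherent — features separate the classes
they were trained on and errors concentrate at window-quantized boundaries —
not that the same parameters transfer to clinical images.

## Problem sizes and defaults

Unit tests use 96×96 phantoms (16×16 windows of 6×6) and 16×16 random
images for oracle equivalence; the segmentation-error property uses the
512×512 preset matching the typical acquisition size, five seed pairs,
with the held-out misclassification bound at 8 %. Observed errors are ≈ 3–4
%, dominated by boundary-straddling windows (the tissue/annulus perimeter is
≈ 2.5 % of the frame at 512×512).

## Known limitations

- Interval models ignore feature correlations within a class (axis-aligned
  boxes); heavily overlapping class distributions degrade the vote.
- The cross-level borrowing can misvote near boundaries when a structure is
  thinner than the RW at L1 (e.g. a 6-pixel annulus at 96×96).
- Border windows renormalize over truncated rings, which slightly biases
  second-order feedbacks at image edges.
- Only single-channel integer imagery is supported; DICOM/NIfTI readers and
  acquisition-specific preprocessing are out of scope.
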