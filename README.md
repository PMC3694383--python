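# mritex

Generalized first- and second-order statistical texture operators for
grayscale (MRI-style) images, with a supervised interval model for tissue
segmentation and a synthetic phantom generator so everything is testable
without clinical data.

## Who this is for

Researchers in medical image analysis who want parametric, inspectable
texture features — the kind used to separate background, tissue and
bone/skull in transversal MR slices — rather than opaque learned features.
The package is a library first (sklearn-style estimators) with a thin
`mritex` command-line tool on top.

## The method

An image is browsed by a fixed **recognition window** (RW, default 6×6
pixels, non-overlapping, row-major). Each window is reduced to a set of
scalar feedbacks *Q<sub>j,f</sub>* = *f*(p₀,…,pₙ), one per operator *f*,
producing a subsampled **feature map** per operator (a 48×48 image under a
6×6 RW becomes an 8×8 map). Analysis is repeated on a 2× mean-subsampled
pyramid level (L0, L1).

**First-order operators** act on the window histogram *p(i)*, *i* ∈ [0, L−1]:

- moment M(n₁) = Σ i^{n₁} p(i) (n₁=1: the window mean)
- central moment C(n₂) = Σ (i − M₁)^{n₂} p(i) (n₂=2: the variance)

**Second-order operators** act on an all-directions co-occurrence matrix:
every window pixel is the center of a **discrete circumference** of radius
*d* (the Chebyshev square ring, 8·d points — 16 at d=2), and each ordered
(center, ring-partner) pair increments the L×L matrix *p_d(i,j)*. Ring
partners are looked up in the full image, so context around the window
contributes. A 3×3 window at d=2 with interior context contributes exactly
9 × 16 = 144 increments. On *p_d* the package computes generalized
homogeneity HG, contrast CT, inverse difference ID, entropy ET, correlation
CR and difference entropy DE (see `docs/methods.md` for the formulas and
parameter conventions).

**Interval model.** Training reduces labelled images to per-window operator
feedbacks; each class keeps a quantile-trimmed interval per (operator,
pyramid level). At classification, operators whose value falls inside a
class's interval vote for it, weighted `1 + mean pairwise dependence` to the
other matching operators (dependence levels 1–4 from a fixed operator
dependence table), and the highest-scoring class is painted over the window.

## Worked example

```python
from mritex import (IntervalTextureClassifier, brainlike_spec, make_phantom,
                    segmentation_error)

train_img, train_lab = make_phantom(brainlike_spec(512, 512, seed=1))
test_img,  test_lab  = make_phantom(brainlike_spec(512, 512, seed=2))

clf = IntervalTextureClassifier(ops="brain", levels=2, quantile=0.01)
clf.fit([train_img], [train_lab])
pred = clf.predict(test_img)

res = segmentation_error(pred, test_lab)
print(f"segmentation error: {res.error:.4f}  ({res.n_evaluated} pixels)")
for c, oe in sorted(res.per_class.items()):
    print(f"  class {c}: over={oe['over']:.4f}  under={oe['under']:.4f}")
```

Output:

```
segmentation error: 0.0339  (260100 pixels)
  class 0: over=0.0411  under=0.0279
  class 1: over=0.0083  under=0.0143
  class 2: over=0.0599  under=0.0849
```

The model was fitted on one 512×512 brain-like phantom (dark noisy
background = class 0, textured tissue disk = class 1, bright skull-like
annulus = class 2) and applied to an independently seeded phantom: 3.4 % of
evaluated pixels are misclassified, almost entirely in windows straddling
region boundaries; per class, `over` is the fraction of spurious pixels and
`under` the fraction of missed pixels relative to the true region size.

The same pipeline from the shell:

```
mritex phantom --height 512 --width 512 --seed 1 --out train.png --labels train_lab.png
mritex phantom --height 512 --width 512 --seed 2 --out test.png  --labels test_lab.png
mritex fit     --image train.png --labels train_lab.png --preset brain --out model.json
mritex segment --image test.png  --model model.json --out seg.png
mritex score   --pred seg.png --truth test_lab.png
```

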