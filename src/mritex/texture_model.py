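"""Supervised interval texture model with dependence-weighted voting.

Training reduces each labelled image to per-window operator feedbacks; for
every (class, operator, pyramid level) the model keeps a numeric interval
(quantile-trimmed range) of the feedbacks observed over that class's
windows.  The set of intervals *is* the mathematical model of the task.

Classification of a window checks each operator value against each class's
interval and lets matching operators vote.  Operators are not independent:
a printed pairwise dependence table (levels 1 = low ... 4 = high) states how
strongly any two operators must be evaluated jointly.  A matching operator's
vote is weighted ``1 + mean dependence to the other operators that also
matched``, so coherent groups of strongly dependent operators dominate
isolated accidental matches.  The highest-scoring class wins; ties break
deterministically toward the smaller class id.

Pyramid levels vote independently: an L0 window additionally borrows the
feature values of the L1 window containing its (down-scaled) center, with
same-name operators across levels treated as strongly dependent (level 4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .feature_space import FeatureSpace, build_feature_space, compute_feature_maps
from .image_io import GrayImage, LabelMap
from .second_order import OPERATOR_NAMES, OperatorSpec
from .windowing import WindowSpec, pyramid, window_grid_shape

__all__ = ["DependenceTable", "DEFAULT_DEPENDENCE", "TextureModel",
           "MARGIN_LABEL", "fit_interval_model", "classify_window",
           "segment_image", "segmentation_error", "SegmentationError",
           "IntervalTextureClassifier", "select_operator_params"]

#: Reserved label painted on margin pixels not covered by any full window.
MARGIN_LABEL = 255

# Pairwise dependence levels between the eight operator families,
# rows/cols ordered as OPERATOR_NAMES = (M, C, HG, CT, ID, ET, CR, DE);
# 0 on the diagonal (undefined).
_DEP_VALUES = np.array([
    [0, 4, 3, 3, 2, 2, 1, 2],
    [4, 0, 2, 3, 2, 3, 2, 2],
    [3, 2, 0, 4, 3, 3, 1, 1],
    [3, 3, 4, 0, 3, 2, 2, 2],
    [2, 2, 3, 3, 0, 4, 3, 2],
    [2, 3, 3, 2, 4, 0, 3, 3],
    [1, 2, 1, 2, 3, 3, 0, 4],
    [2, 2, 1, 2, 2, 3, 4, 0],
], dtype=float)

#: Dependence assumed between the same operator family at two pyramid levels.
_SAME_FAMILY_CROSS_LEVEL = 4.0


@dataclass(frozen=True)
class DependenceTable:
    """Symmetric pairwise dependence levels (1..4) between operator families."""

    values: np.ndarray = field(default_factory=lambda: _DEP_VALUES.copy())

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (8, 8):
            raise ValueError("dependence table must be 8 x 8")
        off = v[~np.eye(8, dtype=bool)]
        if off.min() < 1 or off.max() > 4:
            raise ValueError("off-diagonal dependence levels must lie in 1..4")
        if not np.array_equal(v, v.T):
            raise ValueError("dependence table must be symmetric")
        object.__setattr__(self, "values", v)

    def level(self, a: str, b: str) -> float:
        if a == b:
            raise ValueError("dependence of an operator with itself is undefined")
        return float(self.values[OPERATOR_NAMES.index(a), OPERATOR_NAMES.index(b)])


DEFAULT_DEPENDENCE = DependenceTable()


@dataclass
class TextureModel:
    """Per-(class, operator, level) intervals plus the specs that made them."""

    classes: list
    ops: list
    window: WindowSpec
    levels: int
    intervals: np.ndarray  # (n_classes, n_ops, levels, 2)
    quantile: float = 0.01
    margin_label: int = MARGIN_LABEL

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        expected = (len(self.classes), len(self.ops), self.levels, 2)
        if iv.shape != expected:
            raise ValueError(f"intervals must have shape {expected}, got {iv.shape}")
        if np.any(iv[..., 0] > iv[..., 1]):
            raise ValueError("interval low bounds must not exceed high bounds")
        if self.margin_label in self.classes:
            raise ValueError("margin label collides with a class id")
        object.__setattr__(self, "intervals", iv)

    def to_json(self) -> str:
        return json.dumps({
            "classes": [int(c) for c in self.classes],
            "ops": [op.to_dict() for op in self.ops],
            "window": {"height": self.window.height, "width": self.window.width,
                       "stride_rows": self.window.stride_rows,
                       "stride_cols": self.window.stride_cols},
            "levels": self.levels,
            "quantile": self.quantile,
            "margin_label": self.margin_label,
            "intervals": self.intervals.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TextureModel":
        data = json.loads(text)
        w = data["window"]
        return cls(
            classes=list(data["classes"]),
            ops=[OperatorSpec.from_dict(o) for o in data["ops"]],
            window=WindowSpec(w["height"], w["width"], w["stride_rows"], w["stride_cols"]),
            levels=int(data["levels"]),
            intervals=np.asarray(data["intervals"], dtype=float),
            quantile=float(data["quantile"]),
            margin_label=int(data["margin_label"]),
        )


# ---------------------------------------------------------------------------
# training helpers

def _as_image(x, levels: int = 256) -> GrayImage:
    return x if isinstance(x, GrayImage) else GrayImage(np.asarray(x), levels=levels)


def _as_labels(y) -> LabelMap:
    return y if isinstance(y, LabelMap) else LabelMap(np.asarray(y))


def _window_classes(labels: np.ndarray, classes: list, footprint: tuple[int, int],
                    strides: tuple[int, int], grid: tuple[int, int]) -> np.ndarray:
    """Majority pixel label per window footprint; -1 where the vote ties."""
    fh, fw = footprint
    sr, sc = strides
    rows, cols = grid
    counts = np.empty((len(classes), rows, cols), dtype=np.int64)
    for ci, c in enumerate(classes):
        mask = (labels == c).astype(np.int64)
        sw = sliding_window_view(mask, (fh, fw))[::sr, ::sc][:rows, :cols]
        counts[ci] = sw.sum(axis=(2, 3))
    best = counts.max(axis=0)
    winner = counts.argmax(axis=0)
    tied = (counts == best[None]).sum(axis=0) > 1
    out = np.asarray(classes, dtype=np.int64)[winner]
    out[tied] = -1
    return out


def _space_window_classes(space: FeatureSpace, label_maps: dict, classes: list) -> dict:
    """Window-class grids keyed (image_id, level), majority over source labels."""
    out = {}
    w = space.window
    for img_id in space.image_ids:
        labels = _as_labels(label_maps[img_id]).labels
        for lvl in range(space.levels):
            fm = space.maps[(img_id, 0, lvl)]
            scale = 2 ** lvl
            out[(img_id, lvl)] = _window_classes(
                labels, classes,
                footprint=(w.height * scale, w.width * scale),
                strides=(w.stride_rows * scale, w.stride_cols * scale),
                grid=fm.values.shape)
    return out


def fit_interval_model(space: FeatureSpace, label_maps: dict,
                       classes: list | None = None,
                       quantile: float = 0.01,
                       margin_label: int = MARGIN_LABEL) -> TextureModel:
    """Fit per-(class, operator, level) intervals from a labelled feature space.

    A window belongs to the class holding the majority of its pixels' labels
    (ties excluded from training).  The interval is the
    ``[quantile, 1 - quantile]`` range of the operator's values over that
    class's windows; ``quantile=0`` yields the exact min/max.
    """
    if not 0 <= quantile < 0.5:
        raise ValueError("quantile must lie in [0, 0.5)")
    if classes is None:
        cs: set = set()
        for lm in label_maps.values():
            cs.update(_as_labels(lm).classes)
        classes = sorted(cs)
    classes = [int(c) for c in classes]
    wc = _space_window_classes(space, label_maps, classes)
    n_ops = len(space.ops)
    intervals = np.empty((len(classes), n_ops, space.levels, 2))
    for ci, c in enumerate(classes):
        for lvl in range(space.levels):
            n_windows = sum(int((wc[(img_id, lvl)] == c).sum())
                            for img_id in space.image_ids)
            if n_windows == 0:
                raise ValueError(f"class {c} has no training windows at level {lvl}")
        for oi in range(n_ops):
            for lvl in range(space.levels):
                vals = np.concatenate([
                    space.maps[(img_id, oi, lvl)].values[wc[(img_id, lvl)] == c]
                    for img_id in space.image_ids])
                intervals[ci, oi, lvl] = np.quantile(vals, [quantile, 1.0 - quantile])
    return TextureModel(classes, list(space.ops), space.window, space.levels,
                        intervals, quantile, margin_label)


# ---------------------------------------------------------------------------
# classification

def _vote_dependence(ops: list, levels: int,
                     dep: DependenceTable) -> np.ndarray:
    """Dependence matrix over the (operator, level) vote axis, diagonal 0."""
    names = [op.name for op in ops for _ in range(levels)]
    nv = len(names)
    D = np.zeros((nv, nv))
    for a in range(nv):
        for b in range(nv):
            if a == b:
                continue
            D[a, b] = (_SAME_FAMILY_CROSS_LEVEL if names[a] == names[b]
                       else dep.level(names[a], names[b]))
    return D


def _vote_scores(matched: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Scores from boolean match flags, shape (n_classes, n_votes, n_windows)."""
    n_classes, nv, n = matched.shape
    scores = np.empty((n_classes, n))
    for ci in range(n_classes):
        M = matched[ci].astype(float)
        num = D @ M
        tot = M.sum(axis=0)
        den = np.maximum(tot[None, :] - M, 1.0)
        scores[ci] = (M * (1.0 + num / den)).sum(axis=0)
    return scores


def _feature_order(model: TextureModel):
    return [(oi, lvl) for oi in range(len(model.ops)) for lvl in range(model.levels)]


def classify_window(features, model: TextureModel,
                    dep: DependenceTable = DEFAULT_DEPENDENCE) -> int:
    """Classify one window from its per-(operator, level) feature values.

    ``features`` is a mapping ``(op_index, level) -> value`` (or a flat
    sequence in ``(op major, level minor)`` order) covering every operator
    of the model.  Deterministic: ties break toward the smaller class id,
    and the result is invariant to operator order.
    """
    order = _feature_order(model)
    if isinstance(features, dict):
        vec = np.array([features[key] for key in order], dtype=float)
    else:
        vec = np.asarray(features, dtype=float)
        if vec.shape != (len(order),):
            raise ValueError(f"expected {len(order)} feature values")
    iv = model.intervals.reshape(len(model.classes), -1, 2)
    matched = ((vec[None, :] >= iv[..., 0]) & (vec[None, :] <= iv[..., 1]))
    D = _vote_dependence(model.ops, model.levels, dep)
    scores = _vote_scores(matched[:, :, None], D)[:, 0]
    return int(model.classes[int(np.argmax(scores))])


def _level_feature_grids(img: GrayImage, model: TextureModel) -> np.ndarray:
    """Per-L0-window features, shape (n_ops, levels, rows0, cols0).

    Level-l values are borrowed from the level-l window containing the
    down-scaled center of each L0 window.
    """
    w = model.window
    level_imgs = pyramid(img, model.levels)
    rows0, cols0 = window_grid_shape(img.height, img.width, w)
    if rows0 == 0 or cols0 == 0:
        raise ValueError("window larger than image")
    F = np.empty((len(model.ops), model.levels, rows0, cols0))
    for lvl, level_img in enumerate(level_imgs):
        fms = compute_feature_maps(level_img, model.ops, w, level=lvl)
        rows_l, cols_l = fms[0].values.shape
        if lvl == 0:
            for oi, fm in enumerate(fms):
                F[oi, 0] = fm.values
            continue
        scale = 2 ** lvl
        cr = (np.arange(rows0) * w.stride_rows + w.height // 2) // scale
        cc = (np.arange(cols0) * w.stride_cols + w.width // 2) // scale
        ri = np.minimum(cr // w.stride_rows, rows_l - 1)
        ci = np.minimum(cc // w.stride_cols, cols_l - 1)
        for oi, fm in enumerate(fms):
            F[oi, lvl] = fm.values[np.ix_(ri, ci)]
    return F


def segment_image(img: GrayImage, model: TextureModel,
                  dep: DependenceTable = DEFAULT_DEPENDENCE) -> LabelMap:
    """Per-window classification painted back to per-pixel labels.

    Discarded margin pixels (right/bottom remainders not covered by any full
    window) receive the reserved margin label.
    """
    w = model.window
    F = _level_feature_grids(img, model)
    n_ops, levels, rows, cols = F.shape
    vec = F.reshape(n_ops * levels, -1)
    iv = model.intervals.reshape(len(model.classes), -1, 2)
    matched = ((vec[None] >= iv[..., 0][..., None]) & (vec[None] <= iv[..., 1][..., None]))
    D = _vote_dependence(model.ops, model.levels, dep)
    scores = _vote_scores(matched, D)
    labels_grid = np.asarray(model.classes, dtype=np.int64)[scores.argmax(axis=0)]
    labels_grid = labels_grid.reshape(rows, cols)

    out = np.full(img.shape, model.margin_label, dtype=np.int64)
    if not w.overlapping:
        painted = np.repeat(np.repeat(labels_grid, w.height, axis=0), w.width, axis=1)
        out[:rows * w.height, :cols * w.width] = painted
    else:
        for r in range(rows):
            for c in range(cols):
                r0, c0 = r * w.stride_rows, c * w.stride_cols
                out[r0:r0 + w.height, c0:c0 + w.width] = labels_grid[r, c]
    return LabelMap(out)


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class SegmentationError:
    """Misclassified-pixel fraction plus per-class over/under segmentation."""

    error: float
    n_evaluated: int
    per_class: dict  # class -> {"over": fraction, "under": fraction}

    def __float__(self) -> float:
        return self.error


def segmentation_error(pred: LabelMap, truth: LabelMap,
                       margin_label: int = MARGIN_LABEL) -> SegmentationError:
    """Fraction of evaluated pixels whose predicted label differs from truth.

    Margin-labelled pixels (in either map) are excluded.  Per class c,
    ``over`` counts pixels predicted c but truly something else, ``under``
    pixels truly c but predicted otherwise, both relative to the true pixel
    count of c (over- and under-segmentation of that object).
    """
    p, t = _as_labels(pred).labels, _as_labels(truth).labels
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    mask = (p != margin_label) & (t != margin_label)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no pixels to evaluate outside the margin")
    pm, tm = p[mask], t[mask]
    err = float(np.mean(pm != tm))
    per_class = {}
    for c in np.union1d(np.unique(pm), np.unique(tm)).tolist():
        true_c = int((tm == c).sum())
        over = int(((pm == c) & (tm != c)).sum())
        under = int(((tm == c) & (pm != c)).sum())
        denom = max(true_c, 1)
        per_class[int(c)] = {"over": over / denom, "under": under / denom}
    return SegmentationError(err, n, per_class)


# ---------------------------------------------------------------------------
# parameter selection (automated stand-in for interactive expert tuning)

def _interval_overlap(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized overlap of two [low, high] intervals in [0, 1]."""
    inter = min(a[1], b[1]) - max(a[0], b[0])
    union = max(a[1], b[1]) - min(a[0], b[0])
    if union <= 0:
        return 1.0 if inter >= 0 else 0.0
    return max(0.0, inter) / union


def select_operator_params(images: list, label_maps: list, region: str,
                           window: WindowSpec, levels: int = 2,
                           quantile: float = 0.01) -> list:
    """Pick one configuration per operator family from a body-region grid.

    Deterministic grid search scored by the summed normalized interval
    overlap across class pairs and pyramid levels (lower = better class
    separation); the score is additive over operators, so the choice is made
    family by family.  First candidate wins ties.
    """
    from .presets import grid_ops

    grids = grid_ops(region)
    all_specs = [spec for fam in grids.values() for spec in fam]
    ids = list(range(len(images)))
    imgs = [_as_image(x) for x in images]
    space = build_feature_space(imgs, all_specs, window, levels, image_ids=ids)
    lmaps = {i: _as_labels(label_maps[i]) for i in ids}
    classes: list = sorted({c for lm in lmaps.values() for c in lm.classes})
    wc = _space_window_classes(space, lmaps, classes)

    def candidate_score(oi: int) -> float:
        score = 0.0
        for lvl in range(levels):
            ivs = []
            for c in classes:
                vals = np.concatenate([
                    space.maps[(i, oi, lvl)].values[wc[(i, lvl)] == c] for i in ids])
                if vals.size == 0:
                    return np.inf
                ivs.append(np.quantile(vals, [quantile, 1.0 - quantile]))
            for a in range(len(ivs)):
                for b in range(a + 1, len(ivs)):
                    score += _interval_overlap(ivs[a], ivs[b])
        return score

    chosen = []
    offset = 0
    for fam_specs in grids.values():
        scores = [candidate_score(offset + k) for k in range(len(fam_specs))]
        chosen.append(fam_specs[int(np.argmin(scores))])
        offset += len(fam_specs)
    return chosen


# ---------------------------------------------------------------------------
# sklearn estimator

class IntervalTextureClassifier(BaseEstimator):
    """Interval-based texture segmenter with dependence-weighted voting.

    Fit on (image, label map) pairs; predict returns a per-pixel LabelMap
    for each input image.

    Parameters
    ----------
    ops : str or list of OperatorSpec, default "brain"
        Operator configurations, or a body-region preset name.
    window : int or (int, int), default 6
        Recognition-window size.
    stride : int or (int, int), optional
        Scanning stride (defaults to the window size: no overlap).
    levels : int, default 2
        Pyramid levels used both in training and at classification.
    quantile : float, default 0.01
        Trim fraction for the class intervals (0 = exact min/max).
    param_search : bool, default False
        When ``ops`` is a preset name, run the deterministic per-family grid
        search over that region's parameter grid instead of the defaults.
    margin_label : int, default 255
        Reserved label for pixels not covered by any full window.
    """

    def __init__(self, ops="brain", window=6, stride=None, levels=2,
                 quantile=0.01, param_search=False, margin_label=MARGIN_LABEL):
        self.ops = ops
        self.window = window
        self.stride = stride
        self.levels = levels
        self.quantile = quantile
        self.param_search = param_search
        self.margin_label = margin_label

    def _window_spec(self) -> WindowSpec:
        wh, ww = ((self.window, self.window) if np.isscalar(self.window)
                  else self.window)
        if self.stride is None:
            return WindowSpec(wh, ww)
        sr, sc = ((self.stride, self.stride) if np.isscalar(self.stride)
                  else self.stride)
        return WindowSpec(wh, ww, sr, sc)

    def fit(self, X, y):
        from .presets import default_ops

        imgs = [_as_image(x) for x in ([X] if isinstance(X, GrayImage) else list(X))]
        lmaps = [_as_labels(l) for l in ([y] if isinstance(y, LabelMap) else list(y))]
        if len(imgs) != len(lmaps):
            raise ValueError("X and y must pair one label map per image")
        wspec = self._window_spec()
        if isinstance(self.ops, str):
            if self.param_search:
                ops = select_operator_params(imgs, lmaps, self.ops, wspec,
                                             self.levels, self.quantile)
            else:
                ops = default_ops(self.ops)
        else:
            ops = list(self.ops)
        ids = list(range(len(imgs)))
        space = build_feature_space(imgs, ops, wspec, self.levels, image_ids=ids)
        self.model_ = fit_interval_model(space, dict(zip(ids, lmaps)),
                                         quantile=self.quantile,
                                         margin_label=self.margin_label)
        self.ops_ = ops
        self.classes_ = np.asarray(self.model_.classes)
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise RuntimeError("classifier is not fitted")
        single = isinstance(X, GrayImage) or (
            not isinstance(X, (list, tuple)) and np.asarray(X).ndim == 2)
        imgs = [X] if single else list(X)
        out = [segment_image(_as_image(x), self.model_) for x in imgs]
        return out[0] if single else out

    def score(self, X, y):
        """Mean pixel accuracy (1 - segmentation error) over the inputs."""
        preds = self.predict(X)
        if isinstance(preds, LabelMap):
            preds, y = [preds], [y]
        errs = [segmentation_error(p, _as_labels(t), self.margin_label).error
                for p, t in zip(preds, y)]
        return 1.0 - float(np.mean(errs))
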