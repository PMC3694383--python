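import numpy as np
import pytest

from mritex import (DEFAULT_DEPENDENCE, MARGIN_LABEL, DependenceTable,
                    GrayImage, IntervalTextureClassifier, LabelMap,
                    TextureModel, WindowSpec, brainlike_spec, classify_window,
                    default_ops, fit_interval_model, make_phantom,
                    segment_image, segmentation_error, build_feature_space)
from mritex.texture_model import _space_window_classes


@pytest.fixture(scope="module")
def small_phantom():
    return make_phantom(brainlike_spec(96, 96, seed=11))


def _space_for(img, ops, levels=1):
    return build_feature_space([img], ops, WindowSpec(), levels=levels)


class TestDependenceTable:
    def test_levels_in_range_and_symmetric(self):
        t = DEFAULT_DEPENDENCE
        v = t.values
        off = v[~np.eye(8, dtype=bool)]
        assert off.min() >= 1 and off.max() <= 4
        np.testing.assert_array_equal(v, v.T)

    def test_strongly_joint_pairs(self):
        assert DEFAULT_DEPENDENCE.level("M", "C") == 4
        assert DEFAULT_DEPENDENCE.level("HG", "CT") == 4
        assert DEFAULT_DEPENDENCE.level("ID", "ET") == 4
        assert DEFAULT_DEPENDENCE.level("CR", "DE") == 4
        assert DEFAULT_DEPENDENCE.level("M", "CR") == 1

    def test_diagonal_undefined(self):
        with pytest.raises(ValueError):
            DEFAULT_DEPENDENCE.level("M", "M")

    def test_asymmetric_table_rejected(self):
        v = DEFAULT_DEPENDENCE.values.copy()
        v[0, 1] = 3
        with pytest.raises(ValueError):
            DependenceTable(v)


class TestFitIntervalModel:
    def test_quantile_zero_gives_exact_min_max(self, rng):
        img = GrayImage(rng.integers(0, 256, (48, 48)), 256)
        labels = LabelMap(np.zeros((48, 48), dtype=int))
        ops = [default_ops("brain")[0]]  # M(1)
        space = _space_for(img, ops)
        model = fit_interval_model(space, {0: labels}, quantile=0.0)
        vals = space.maps[(0, 0, 0)].values
        assert model.intervals[0, 0, 0, 0] == vals.min()
        assert model.intervals[0, 0, 0, 1] == vals.max()

    def test_single_class_spans_observed_range(self, rng):
        img = GrayImage(rng.integers(0, 16, (24, 24)), 16)
        labels = LabelMap(np.full((24, 24), 3, dtype=int))
        space = _space_for(img, default_ops("brain"))
        model = fit_interval_model(space, {0: labels}, quantile=0.0)
        assert model.classes == [3]
        assert np.all(model.intervals[..., 0] <= model.intervals[..., 1])

    def test_disjoint_textures_give_disjoint_mean_intervals(self):
        px = np.full((48, 48), 10)
        px[:, 24:] = 200
        labels = np.zeros((48, 48), dtype=int)
        labels[:, 24:] = 1
        space = _space_for(GrayImage(px, 256), [default_ops("brain")[0]])
        model = fit_interval_model(space, {0: LabelMap(labels)}, quantile=0.0)
        lo0, hi0 = model.intervals[0, 0, 0]
        lo1, hi1 = model.intervals[1, 0, 0]
        assert hi0 < lo1

    def test_missing_class_raises_with_name(self, rng):
        img = GrayImage(rng.integers(0, 16, (24, 24)), 16)
        labels = LabelMap(np.zeros((24, 24), dtype=int))
        space = _space_for(img, [default_ops("brain")[0]])
        with pytest.raises(ValueError, match="class 7"):
            fit_interval_model(space, {0: labels}, classes=[0, 7])

    def test_training_windows_match_own_intervals_at_quantile_zero(self, small_phantom):
        img, lab = small_phantom
        ops = default_ops("brain")
        space = _space_for(img, ops, levels=2)
        model = fit_interval_model(space, {0: lab}, quantile=0.0)
        wc = _space_window_classes(space, {0: lab}, model.classes)
        for lvl in range(2):
            classes_grid = wc[(0, lvl)]
            for oi in range(len(ops)):
                vals = space.maps[(0, oi, lvl)].values
                for ci, c in enumerate(model.classes):
                    sel = vals[classes_grid == c]
                    lo, hi = model.intervals[ci, oi, lvl]
                    assert np.all((sel >= lo) & (sel <= hi))

    def test_json_round_trip(self, small_phantom):
        img, lab = small_phantom
        space = _space_for(img, default_ops("brain"), levels=2)
        model = fit_interval_model(space, {0: lab})
        back = TextureModel.from_json(model.to_json())
        assert back.classes == model.classes
        assert back.ops == model.ops
        np.testing.assert_allclose(back.intervals, model.intervals)


class TestClassifyWindow:
    def _toy_model(self, ops):
        # class 0 matches M and C only; class 1 matches HG, CT, ID, ET only
        iv = np.zeros((2, 8, 1, 2))
        iv[..., 0], iv[..., 1] = 2.0, 3.0  # default: no match at feature 0.5
        iv[0, 0:2, 0] = [0.0, 1.0]
        iv[1, 2:6, 0] = [0.0, 1.0]
        return TextureModel([0, 1], ops, WindowSpec(), 1, iv)

    def test_unique_full_match_wins(self, small_phantom):
        ops = default_ops("brain")
        iv = np.zeros((2, 8, 1, 2))
        iv[0, :, 0] = [0.0, 1.0]
        iv[1, :, 0] = [5.0, 6.0]
        model = TextureModel([0, 1], ops, WindowSpec(), 1, iv)
        assert classify_window([0.5] * 8, model) == 0
        assert classify_window([5.5] * 8, model) == 1

    def test_dependence_weighted_majority(self):
        """Two strongly joint matches (M,C) lose to four jointly dependent
        matches (HG,CT,ID,ET): 2*(1+4) = 10 < 16.67."""
        model = self._toy_model(default_ops("brain"))
        assert classify_window([0.5] * 8, model) == 1

    def test_operator_order_invariance(self):
        ops = default_ops("brain")
        model = self._toy_model(ops)
        perm = [3, 0, 6, 1, 7, 2, 5, 4]
        iv = model.intervals[:, perm]
        permuted = TextureModel([0, 1], [ops[i] for i in perm], WindowSpec(), 1, iv)
        feats = [0.5] * 8
        assert classify_window(feats, permuted) == classify_window(feats, model)

    def test_tie_breaks_toward_smaller_class_id(self):
        ops = default_ops("brain")
        iv = np.zeros((2, 8, 1, 2))
        iv[:, :, 0] = [0.0, 1.0]  # both classes match everything
        model = TextureModel([0, 1], ops, WindowSpec(), 1, iv)
        assert classify_window([0.5] * 8, model) == 0

    def test_zero_features_classified_as_background(self, small_phantom):
        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain").fit([img], [lab])
        model = clf.model_
        feats = {key: 0.0 for key in
                 [(oi, lvl) for oi in range(8) for lvl in range(2)]}
        assert classify_window(feats, model) == 0


class TestSegmentation:
    def test_constant_background_image(self, small_phantom):
        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain").fit([img], [lab])
        flat = GrayImage(np.full((48, 48), 10), 256)
        pred = segment_image(flat, clf.model_)
        assert np.all(pred.labels == 0)

    def test_margin_painted_with_reserved_label(self, small_phantom):
        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain").fit([img], [lab])
        odd = GrayImage(np.full((50, 50), 10), 256)  # 50 = 8*6 + 2
        pred = segment_image(odd, clf.model_)
        assert np.all(pred.labels[48:, :] == MARGIN_LABEL)
        assert np.all(pred.labels[:, 48:] == MARGIN_LABEL)

    def test_two_region_phantom_recovered_up_to_boundaries(self):
        px = np.full((96, 96), 10)
        px[:, 48:] = 200
        labels = np.zeros((96, 96), dtype=int)
        labels[:, 48:] = 1
        rng = np.random.default_rng(5)
        noisy = np.clip(px + rng.normal(0, 3, px.shape), 0, 255).astype(int)
        img = GrayImage(noisy, 256)
        clf = IntervalTextureClassifier(ops="brain", levels=1,
                                        quantile=0.0).fit([img], [labels])
        pred = clf.predict(img)
        err = segmentation_error(pred, LabelMap(labels))
        assert err.error == 0.0  # boundary aligns with the window grid

    def test_training_image_interior_windows_all_correct(self, small_phantom):
        """With untrimmed intervals, every training window lying wholly inside
        one region is reassigned its own class; residual error concentrates
        on windows straddling region boundaries."""
        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain", levels=1,
                                        quantile=0.0).fit([img], [lab])
        pred = clf.predict(img)
        uniform = np.zeros(lab.shape, dtype=bool)
        for r in range(0, 96, 6):
            for c in range(0, 96, 6):
                blk = lab.labels[r:r + 6, c:c + 6]
                if np.all(blk == blk[0, 0]):
                    uniform[r:r + 6, c:c + 6] = True
        assert uniform.any()
        assert np.all(pred.labels[uniform] == lab.labels[uniform])


class TestSegmentationError:
    def test_identical_maps(self):
        lab = LabelMap(np.arange(4).reshape(2, 2) % 3)
        assert segmentation_error(lab, lab).error == 0.0

    def test_fully_complementary(self):
        a = LabelMap(np.zeros((4, 4), dtype=int))
        b = LabelMap(np.ones((4, 4), dtype=int))
        assert segmentation_error(a, b).error == 1.0

    def test_exact_ten_percent(self):
        truth = np.zeros((10, 10), dtype=int)
        pred = truth.copy()
        pred.ravel()[:10] = 1
        res = segmentation_error(LabelMap(pred), LabelMap(truth))
        assert res.error == pytest.approx(0.10)
        assert res.per_class[1]["over"] == pytest.approx(10 / 1)  # no true 1s -> denom 1
        assert res.per_class[0]["under"] == pytest.approx(0.10)

    def test_margin_excluded(self):
        truth = np.zeros((4, 4), dtype=int)
        pred = np.zeros((4, 4), dtype=int)
        pred[0] = MARGIN_LABEL
        res = segmentation_error(LabelMap(pred), LabelMap(truth))
        assert res.n_evaluated == 12
        assert res.error == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segmentation_error(LabelMap(np.zeros((2, 2), int)),
                               LabelMap(np.zeros((3, 3), int)))


class TestClassifierEstimator:
    def test_held_out_phantom_segmentation(self, small_phantom):
        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain").fit([img], [lab])
        img2, lab2 = make_phantom(brainlike_spec(96, 96, seed=12))
        err = segmentation_error(clf.predict(img2), lab2)
        assert err.error < 0.25  # boundary windows dominate at this tiny size

    def test_score_is_pixel_accuracy(self, small_phantom):
        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain").fit([img], [lab])
        acc = clf.score([img], [lab])
        err = segmentation_error(clf.predict(img), lab).error
        assert acc == pytest.approx(1.0 - err)

    def test_param_search_selects_from_preset_grid(self, small_phantom):
        from mritex.presets import PRESET_GRIDS

        img, lab = small_phantom
        clf = IntervalTextureClassifier(ops="brain", param_search=True,
                                        levels=1).fit([img], [lab])
        assert len(clf.ops_) == 8
        for op in clf.ops_:
            grid = PRESET_GRIDS["brain"][op.name]
            for key, val in op.params.items():
                if key in grid:  # q has a fixed default outside the grids
                    assert val in grid[key]
            if op.d is not None:
                assert op.d in grid["d"]

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError):
            IntervalTextureClassifier().predict(np.zeros((12, 12), dtype=int))
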