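"""Occlusion attribution: oracle equivalence, thresholds, frequency maps."""

import math

import numpy as np
import pytest

from slicemap.attribution import OcclusionConfig, attribute_dataset, frequency_map, \
    neutral_reference, occlusion_scores, patch_starts, sign_adjust, \
    slice_occlusion_summary, subject_threshold
from slicemap.exceptions import ParameterError


def brute_force_occlusion(predict_fn, image, neutral, window, stride):
    """Independent per-pixel enumeration of Eqns' covering-patch mean drop."""
    h, w = image.shape
    rows = list(range(0, h - window + 1, stride))
    if rows[-1] != h - window:
        rows.append(h - window)
    cols = list(range(0, w - window + 1, stride))
    if cols[-1] != w - window:
        cols.append(w - window)
    f0 = float(predict_fn(image[None])[0])
    drops = {}
    for r in rows:
        for c in cols:
            occluded = image.copy()
            occluded[r:r + window, c:c + window] = neutral[r:r + window, c:c + window]
            drops[(r, c)] = f0 - float(predict_fn(occluded[None])[0])
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            covering = [d for (r, c), d in drops.items()
                        if r <= i < r + window and c <= j < c + window]
            out[i, j] = np.mean(covering)
    return out


def linear_sum_model(images):
    return np.asarray(images, dtype=np.float64).reshape(len(images), -1).sum(axis=1)


class TestNeutralReference:
    def test_min_abs_logit_selected(self):
        fake = lambda imgs: np.array([-2.0, 0.1, 3.0])
        ref = neutral_reference(fake, np.zeros((3, 4, 4)))
        assert ref.index == 1

    def test_tie_broken_by_lowest_index(self):
        fake = lambda imgs: np.array([-0.1, 0.1])
        assert neutral_reference(fake, np.zeros((2, 4, 4))).index == 0

    def test_single_candidate(self):
        fake = lambda imgs: np.array([5.0])
        assert neutral_reference(fake, np.zeros((1, 4, 4))).index == 0

    def test_empty_pool_rejected(self):
        with pytest.raises(ParameterError):
            neutral_reference(lambda imgs: np.array([]), np.zeros((0, 4, 4)))


class TestOcclusionScores:
    def test_constant_model_all_zero(self):
        cfg = OcclusionConfig(window=5, stride=2)
        image = np.random.default_rng(0).random((16, 16)).astype(np.float32)
        scores = occlusion_scores(lambda imgs: np.full(len(imgs), 1.7), image,
                                  np.zeros_like(image), cfg)
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    @pytest.mark.parametrize("shape,window,stride", [
        ((16, 16), 7, 3),
        ((32, 32), 15, 5),
        ((20, 26), 9, 4),
    ])
    def test_linear_model_matches_brute_force(self, shape, window, stride):
        rng = np.random.default_rng(1)
        image = rng.random(shape).astype(np.float32)
        neutral = rng.random(shape).astype(np.float32)
        cfg = OcclusionConfig(window=window, stride=stride)
        fast = occlusion_scores(linear_sum_model, image, neutral, cfg)
        slow = brute_force_occlusion(linear_sum_model, image, neutral, window, stride)
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_random_small_model_matches_brute_force(self):
        from slicemap.models import build_cnn2d
        model = build_cnn2d(input_shape=(24, 24), seed=7)
        rng = np.random.default_rng(2)
        image = rng.random((24, 24)).astype(np.float32)
        neutral = rng.random((24, 24)).astype(np.float32)
        cfg = OcclusionConfig(window=9, stride=4)
        fast = occlusion_scores(model.predict_logits, image, neutral, cfg)
        slow = brute_force_occlusion(model.predict_logits, image, neutral, 9, 4)
        np.testing.assert_allclose(fast, slow, atol=1e-5)

    def test_interior_coverage_count_window15_stride5(self):
        starts = patch_starts(64, 15, 5)
        covering = [s for s in starts if s <= 30 <= s + 14]
        assert covering == [20, 25, 30]
        assert len(covering) ** 2 == 9  # both axes

    def test_flush_to_border_covers_every_pixel(self):
        starts = patch_starts(32, 15, 5)
        assert starts[-1] == 17
        covered = set()
        for s in starts:
            covered.update(range(s, s + 15))
        assert covered == set(range(32))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            occlusion_scores(linear_sum_model, np.zeros((16, 16)), np.zeros((16, 17)),
                             OcclusionConfig(window=5, stride=2))


class TestSignAdjust:
    def test_positive_class_identity(self):
        raw = np.array([[0.5, -0.7]])
        np.testing.assert_array_equal(sign_adjust(raw, 1), raw)

    def test_negative_class_negation(self):
        assert sign_adjust(np.array([[-0.7]]), 0)[0, 0] == pytest.approx(0.7)

    def test_zero_grid(self):
        np.testing.assert_array_equal(sign_adjust(np.zeros((3, 3)), 0), np.zeros((3, 3)))


class TestSubjectThreshold:
    def test_400_distinct_values_retain_20(self):
        rng = np.random.default_rng(0)
        grid = rng.permutation(400).astype(float).reshape(20, 20)
        tau, indicator = subject_threshold(grid, 0.05)
        assert indicator.sum() == 20
        assert np.all(grid[indicator] >= tau)

    def test_constant_grid_all_retained(self):
        _, indicator = subject_threshold(np.full((5, 5), 2.0), 0.05)
        assert indicator.all()

    def test_minimum_count_property(self):
        rng = np.random.default_rng(1)
        for size in (10, 33, 100, 481):
            grid = rng.random(size)
            _, ind = subject_threshold(grid, 0.05)
            assert ind.sum() >= math.ceil(0.05 * size)


class TestFrequencyMap:
    def test_single_subject_equals_indicator(self):
        ind = np.random.default_rng(0).random((8, 8)) > 0.5
        fm = frequency_map([ind])
        np.testing.assert_array_equal(fm.values, ind.astype(float))

    def test_two_disjoint_subjects(self):
        a = np.zeros((4, 4), dtype=bool)
        b = np.zeros((4, 4), dtype=bool)
        a[0, 0] = True
        b[3, 3] = True
        fm = frequency_map([a, b])
        assert set(np.unique(fm.values)) == {0.0, 0.5}

    def test_all_ones_smooth_to_one(self):
        fm = frequency_map([np.ones((6, 6), dtype=bool)] * 3)
        np.testing.assert_allclose(fm.values, 1.0)
        np.testing.assert_allclose(fm.smoothed, 1.0, atol=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        fm = frequency_map([rng.random((5, 5)) > 0.5 for _ in range(7)])
        assert fm.values.min() >= 0.0 and fm.values.max() <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            frequency_map([np.zeros((3, 3)), np.zeros((4, 4))])


class TestSliceSummary:
    def test_single_subject(self):
        grid = np.zeros((4, 4))
        grid[2, 2] = 0.9
        assert slice_occlusion_summary([grid]) == pytest.approx(0.9)

    def test_zero_grids(self):
        assert slice_occlusion_summary([np.zeros((3, 3))] * 4 ) == 0.0

    def test_permutation_invariant(self):
        rng = np.random.default_rng(3)
        grids = [rng.random((5, 5)) for _ in range(6)]
        assert slice_occlusion_summary(grids) == pytest.approx(
            slice_occlusion_summary(grids[::-1]))


class TestSignSymmetry:
    def test_label_swap_with_negated_model_keeps_frequency_map(self):
        """Swapping all labels and negating logits leaves F unchanged."""
        rng = np.random.default_rng(4)
        images = rng.random((6, 20, 20)).astype(np.float32)
        labels = np.array([0, 1, 0, 1, 1, 0])
        ids = [f"s{i}" for i in range(6)]
        weights = rng.standard_normal((20, 20))

        def model(imgs):
            return np.einsum("bij,ij->b", np.asarray(imgs, dtype=np.float64), weights)

        def neg_model(imgs):
            return -model(imgs)

        cfg = OcclusionConfig(window=7, stride=4)
        _, fm_a = attribute_dataset(model, images, labels, ids, cfg)
        _, fm_b = attribute_dataset(neg_model, images, 1 - labels, ids, cfg)
        np.testing.assert_allclose(fm_a.values, fm_b.values)
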