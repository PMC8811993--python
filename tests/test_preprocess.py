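"""Unit tests for the image pre-processing operators."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from faleak import (
    AlignmentError,
    align_pair,
    binarize,
    crop_centered,
    isodata_default_threshold,
    leakage_map,
    rolling_ball_subtract,
)
from faleak.synthetic import ScenarioParams, generate_fa_pair

from .oracles import ball_opening_subtract, intermeans_fixed_points

small_images = hnp.arrays(
    np.uint8, hnp.array_shapes(min_dims=2, max_dims=2, min_side=4, max_side=24)
)


class TestCropCentered:
    def test_even_window_convention(self):
        img = np.arange(768 * 768, dtype=np.float64).reshape(768, 768) % 256
        img = img.astype(np.uint8)
        out = crop_centered(img, (384, 384), 384)
        assert out.shape == (384, 384)
        np.testing.assert_array_equal(out, img[192:576, 192:576])

    def test_out_of_bounds_raises(self):
        img = np.zeros((768, 768), dtype=np.uint8)
        with pytest.raises(ValueError, match="out of bounds"):
            crop_centered(img, (100, 100), 384)

    def test_nested_crops_compose(self, rng):
        img = rng.integers(0, 256, (768, 768)).astype(np.uint8)
        nested = crop_centered(crop_centered(img, (400, 300), 384), (192, 192), 240)
        direct = crop_centered(img, (400, 300), 240)
        np.testing.assert_array_equal(nested, direct)

    def test_odd_window(self):
        img = np.arange(49, dtype=np.uint8).reshape(7, 7)
        out = crop_centered(img, (3, 3), 3)
        np.testing.assert_array_equal(out, img[2:5, 2:5])


class TestBinarize:
    def test_extreme_thresholds(self):
        img = np.array([[0, 255], [90, 200]], dtype=np.uint8)
        assert binarize(img, 255).sum() == 0
        np.testing.assert_array_equal(binarize(np.array([[0, 255]], np.uint8), 0),
                                      np.array([[0, 255]], np.uint8))

    @given(img=small_images, threshold=st.integers(0, 255))
    def test_count_conservation(self, img, threshold):
        out = binarize(img, threshold)
        assert set(np.unique(out)) <= {0, 255}
        assert (out == 255).sum() == (img > threshold).sum()


class TestLeakageMap:
    def test_equal_inputs_zero(self):
        b = np.where(np.eye(8) > 0, 255, 0).astype(np.uint8)
        assert leakage_map(b, b).sum() == 0

    def test_full_and_clamped(self):
        full = np.full((4, 4), 255, np.uint8)
        empty = np.zeros((4, 4), np.uint8)
        assert (leakage_map(full, empty) == 255).all()
        assert (leakage_map(empty, full) == 0).all()  # clamped, not -255

    @given(a=small_images, b=st.data())
    def test_antisymmetric_disjoint_supports(self, a, b):
        b5 = binarize(a, 127)
        b1 = binarize(b.draw(hnp.arrays(np.uint8, a.shape)), 127)
        fwd = leakage_map(b5, b1) == 255
        rev = leakage_map(b1, b5) == 255
        assert not (fwd & rev).any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            leakage_map(np.zeros((4, 4), np.uint8), np.zeros((5, 5), np.uint8))


class TestIsodataThreshold:
    def test_two_level_midpoint(self):
        img = np.array([[10] * 8 + [200] * 8] * 4, dtype=np.uint8)
        assert isodata_default_threshold(img) == 105

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            isodata_default_threshold(np.full((8, 8), 7, np.uint8))

    def test_single_bright_pixel_separates(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[0, 0] = 255
        t = isodata_default_threshold(img)
        assert 0 < t < 255

    def test_saturated_extreme_trimming(self):
        # >50% of pixels at 255: the saturated bin must not drag the threshold up
        img = np.concatenate([np.full(600, 255), np.full(200, 20),
                              np.full(200, 80)]).astype(np.uint8).reshape(10, 100)
        t = isodata_default_threshold(img)
        vals = np.concatenate([np.full(200, 20), np.full(200, 80)])
        lo, hi = vals[vals <= t], vals[vals > t]
        assert t == int(np.round((lo.mean() + hi.mean()) / 2))

    @pytest.mark.parametrize("kind", ["uniform", "bimodal", "gaussian"])
    def test_matches_bruteforce_fixed_point(self, kind, rng):
        for _ in range(100):
            if kind == "uniform":
                img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            elif kind == "bimodal":
                img = np.clip(np.concatenate([
                    rng.normal(60, 20, 512), rng.normal(180, 25, 512)
                ]).round(), 0, 255).astype(np.uint8).reshape(32, 32)
            else:
                img = np.clip(rng.normal(120, 40, (32, 32)).round(), 0, 255
                              ).astype(np.uint8)
            t = isodata_default_threshold(img)
            assert t in intermeans_fixed_points(img)


class TestRollingBall:
    def test_constant_image_all_zero(self):
        assert rolling_ball_subtract(np.full((128, 128), 40, np.uint8), 50).max() == 0

    def test_smooth_gradient_residual(self):
        g = np.tile(np.linspace(0, 60, 768), (768, 1)).round().astype(np.uint8)
        assert rolling_ball_subtract(g, 50).max() < 8

    def test_impulse_preserved_on_flat_background(self):
        img = np.full((200, 200), 10, np.uint8)
        img[99:102, 99:102] = 200
        out = rolling_ball_subtract(img, 50)
        assert abs(int(out[100, 100]) - 190) <= 5
        far = out.copy().astype(int)
        far[90:112, 90:112] = 0
        assert far.max() <= 2

    def test_never_increases_and_idempotent(self, rng):
        # smooth scene: even the exact ball-opening is only idempotent on
        # content whose relief is gentle relative to the ball
        from scipy.ndimage import gaussian_filter

        scene = np.clip(gaussian_filter(rng.normal(100, 40, (256, 256)), 8),
                        0, 255).astype(np.uint8)
        o1 = rolling_ball_subtract(scene, 50)
        assert (o1 <= scene).all()
        o2 = rolling_ball_subtract(o1, 50)
        assert np.abs(o1.astype(int) - o2.astype(int)).max() <= 2

    def test_close_to_opening_oracle(self, rng):
        from scipy.ndimage import gaussian_filter

        yy, xx = np.mgrid[0:128, 0:128]
        for radius in (20, 50):
            base = gaussian_filter(rng.normal(80, 50, (128, 128)), 12)
            for _ in range(4):
                r0, c0 = rng.integers(10, 118, 2)
                s = rng.uniform(3, 8)
                base += rng.uniform(30, 90) * np.exp(
                    -((yy - r0) ** 2 + (xx - c0) ** 2) / (2 * s * s))
            img = np.clip(np.round(base), 0, 255).astype(np.uint8)
            ours = rolling_ball_subtract(img, radius).astype(int)
            oracle = ball_opening_subtract(img, radius).astype(int)
            diff = ours - oracle
            assert diff.min() >= -2  # never removes more than the exact ball
            assert diff.max() <= 12
            assert np.abs(diff).mean() <= 3


class TestAlignPair:
    def test_identity_on_same_frame(self):
        pair, _ = generate_fa_pair(ScenarioParams(seed=11))
        _, tf = align_pair(pair.frame_1min, pair.frame_1min)
        assert abs(tf.rotation_deg) < 0.1
        assert abs(tf.translation[0]) < 0.1 and abs(tf.translation[1]) < 0.1

    def test_recovers_known_shift(self):
        pair, truth = generate_fa_pair(
            ScenarioParams(inter_frame_shift=(5.0, 3.0), seed=11))
        aligned, tf = align_pair(pair.frame_1min, pair.frame_5min)
        assert abs(tf.translation[0] - 5.0) < 0.5
        assert abs(tf.translation[1] - 3.0) < 0.5
        # resampled frame should overlay the reference scene closely
        center = (slice(200, 568), slice(200, 568))
        resid = np.abs(aligned[center].astype(int) - pair.frame_1min[center].astype(int))
        assert np.median(resid) < 30

    def test_recovers_known_rotation(self):
        pair, truth = generate_fa_pair(
            ScenarioParams(inter_frame_rotation=2.0, seed=11))
        _, tf = align_pair(pair.frame_1min, pair.frame_5min)
        assert abs(tf.rotation_deg - truth.true_transform.rotation_deg) < 0.25

    def test_featureless_frames_raise(self):
        flat = np.full((512, 512), 30, np.uint8)
        with pytest.raises(AlignmentError):
            align_pair(flat, flat)
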