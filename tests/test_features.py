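"""Tests for the image preprocessing chain and the 19-feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seatbcg.features import (
    FEATURE_NAMES,
    FeatureScaler,
    binarize,
    color_features,
    extract_feature_vector,
    extract_shape,
    geometric_features,
    glcm_features,
    largest_component,
    median_filter3,
    render_frame_image,
    to_grayscale,
)
from seatbcg.synthetic import posture_template


class TestRender:
    def test_constant_frame_uniform_color(self):
        img = render_frame_image(np.full((16, 16), 1.5), upsample=2)
        assert np.all(img.rgb == img.rgb[0, 0])

    def test_max_pressure_maps_to_top_color(self):
        frame = np.zeros((16, 16))
        frame[4, 9] = 3.0  # top of the fixed voltage range
        img = render_frame_image(frame, upsample=1)
        from seatbcg.features import PRESSURE_CMAP

        top = np.rint(np.array(PRESSURE_CMAP(1.0)[:3]) * 255)
        np.testing.assert_array_equal(img.rgb[4, 9], top)

    def test_per_frame_normalisation_absorbs_affine_rescale(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(0.2, 2.5, (16, 16))
        rescaled = 0.5 * frame + 0.1
        a = render_frame_image(frame, upsample=1, per_frame_norm=True)
        b = render_frame_image(rescaled, upsample=1, per_frame_norm=True)
        np.testing.assert_array_equal(a.rgb, b.rgb)
        # with the fixed voltage range the renderings differ
        c = render_frame_image(frame, upsample=1)
        d = render_frame_image(rescaled, upsample=1)
        assert np.any(c.rgb != d.rgb)


class TestGrayscale:
    @pytest.mark.parametrize(
        "rgb,expected",
        [((255, 255, 255), 255), ((0, 0, 0), 0), ((100, 150, 200), 141)],
    )
    def test_luminance_formula(self, rgb, expected):
        img = np.array(rgb, dtype=np.uint8).reshape(1, 1, 3)
        assert to_grayscale(img)[0, 0] == expected


class TestMedianFilter:
    def test_constant_unchanged(self):
        g = np.full((5, 5), 7, dtype=np.uint8)
        np.testing.assert_array_equal(median_filter3(g), g)

    def test_impulse_removed(self):
        g = np.zeros((7, 7), dtype=np.uint8)
        g[3, 3] = 255
        assert median_filter3(g).max() == 0

    def test_matches_bruteforce_neighbourhood_median(self):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 256, (5, 5)).astype(np.uint8)
        out = median_filter3(g)
        padded = np.pad(g, 1, mode="symmetric")
        for r in range(5):
            for c in range(5):
                window = padded[r:r + 3, c:c + 3]
                assert out[r, c] == np.median(window)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            median_filter3(np.zeros((2, 5), dtype=np.uint8))


class TestBinarize:
    def test_two_level_image(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        g.ravel()[:40] = 10
        g.ravel()[40:] = 200
        binary, thr = binarize(g)
        assert 10 <= thr < 200
        assert binary.mean() == pytest.approx(0.6)

    def test_threshold_maximises_between_class_variance(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 256, (12, 12)).astype(np.uint8)
        _, thr = binarize(g)
        # exhaustive search over all candidate thresholds
        best_t, best_v = None, -1.0
        for t in np.unique(g)[:-1]:
            w1 = np.mean(g <= t)
            w2 = 1 - w1
            m1, m2 = g[g <= t].mean(), g[g > t].mean()
            v = w1 * w2 * (m1 - m2) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert thr == pytest.approx(best_t, abs=1.0)

    def test_constant_image_all_foreground(self):
        binary, thr = binarize(np.full((8, 8), 50, dtype=np.uint8))
        assert binary.all()
        assert thr == 49.0

    def test_inversion_swaps_roles(self):
        g = np.zeros((10, 10), dtype=np.uint8)
        g[:5] = 200
        fg, _ = binarize(g)
        fg_inv, _ = binarize(255 - g)
        np.testing.assert_array_equal(fg, ~fg_inv)


class TestExtractShape:
    def test_axis_aligned_rectangle_sides(self):
        binary = np.zeros((40, 40), dtype=bool)
        binary[5:15, 10:25] = True  # 10 x 15 block
        _, (corners, sides) = extract_shape(binary)
        assert sides == pytest.approx((10.0, 15.0), abs=1e-9)

    def test_single_pixel_degenerate(self):
        binary = np.zeros((5, 5), dtype=bool)
        binary[2, 2] = True
        _, (corners, sides) = extract_shape(binary)
        assert sides == pytest.approx((1.0, 1.0))

    def test_disk_rectangle_close_to_diameter(self):
        yy, xx = np.mgrid[0:120, 0:120]
        disk = (yy - 60) ** 2 + (xx - 60) ** 2 <= 40**2
        _, (corners, sides) = extract_shape(disk)
        assert sides[0] == pytest.approx(80, abs=2)
        assert sides[1] == pytest.approx(80, abs=2)

    def test_only_largest_component_kept(self):
        binary = np.zeros((30, 30), dtype=bool)
        binary[2:4, 2:4] = True          # small blob
        binary[10:25, 10:25] = True      # large blob
        contour, (corners, sides) = extract_shape(binary)
        assert contour[:, 0].min() >= 9
        assert sides == pytest.approx((15.0, 15.0), abs=1e-9)

    def test_empty_foreground_rejected(self):
        with pytest.raises(ValueError):
            extract_shape(np.zeros((5, 5), dtype=bool))


class TestGeometricFeatures:
    def test_disk_roundness_near_one(self):
        yy, xx = np.mgrid[0:256, 0:256]
        disk = (yy - 128.0) ** 2 + (xx - 128.0) ** 2 <= 100.0**2
        circumference, area, roundness, hu = geometric_features(disk)
        assert area == disk.sum()
        assert roundness == pytest.approx(1.0, abs=0.1)

    def test_square_perimeter_matches_chain_length(self):
        binary = np.zeros((20, 20), dtype=bool)
        binary[5:15, 5:15] = True  # 10x10 block: boundary ring of 36 px
        circumference, area, roundness, _ = geometric_features(binary)
        assert area == 100
        # chain walks the 36-pixel ring with 4 diagonal-free corners: 36 steps
        assert circumference == pytest.approx(36.0)

    def test_hu_translation_invariance_exact(self):
        binary = np.zeros((64, 64), dtype=bool)
        binary[10:30, 12:26] = True
        shifted = np.roll(np.roll(binary, 20, axis=0), 25, axis=1)
        _, _, _, hu_a = geometric_features(binary)
        _, _, _, hu_b = geometric_features(shifted)
        np.testing.assert_allclose(hu_a, hu_b, rtol=1e-12, atol=1e-300)

    def test_hu_rotation_invariance_90deg(self):
        rng = np.random.default_rng(0)
        binary = np.zeros((80, 80), dtype=bool)
        binary[20:55, 25:50] = True
        binary[30:40, 15:25] = True  # asymmetric appendage, keeps it connected
        _, _, _, hu_a = geometric_features(binary)
        _, _, _, hu_b = geometric_features(np.rot90(binary))
        np.testing.assert_allclose(hu_a, hu_b, rtol=1e-6)


class TestGlcm:
    def test_constant_region(self):
        gray = np.full((8, 8), 100, dtype=np.uint8)
        e_m, e_s, h_m, h_s, i_m, i_s = glcm_features(gray, np.ones((8, 8), bool))
        assert (e_m, h_m, i_m) == pytest.approx((1.0, 0.0, 0.0))
        assert (e_s, h_s, i_s) == pytest.approx((0.0, 0.0, 0.0))

    def test_hand_tabulated_two_level_image(self):
        # 2x2 image, levels after /16 quantisation: [[0, 0], [0, 15]]
        gray = np.array([[0, 0], [0, 255]], dtype=np.uint8)
        mask = np.ones((2, 2), bool)
        e_m, e_s, h_m, h_s, i_m, i_s = glcm_features(gray, mask)
        # horizontal pairs: (0,0), (0,15); vertical: (0,0), (0,15);
        # 45 deg: (0,0); 135 deg: (0,15)  [one pair each]
        # symmetric+normalised per direction:
        # 0/90 deg: p(0,0)=.5, p(0,15)=p(15,0)=.25 -> E=.375, H=1.5, I=112.5
        # 45 deg:   p(0,0)=1 -> E=1, H=0, I=0
        # 135 deg:  p(0,15)=p(15,0)=.5 -> E=.5, H=1, I=225
        assert e_m == pytest.approx(np.mean([0.375, 1.0, 0.375, 0.5]))
        assert h_m == pytest.approx(np.mean([1.5, 0.0, 1.5, 1.0]))
        assert i_m == pytest.approx(np.mean([112.5, 0.0, 112.5, 225.0]))
        assert i_s == pytest.approx(np.std([112.5, 0.0, 112.5, 225.0]))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_statistic_bounds(self, seed):
        rng = np.random.default_rng(seed)
        gray = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        mask = rng.random((10, 10)) < 0.8
        if mask.sum() < 4:
            mask[:] = True
        e_m, e_s, h_m, h_s, i_m, i_s = glcm_features(gray, mask)
        assert 0 < e_m <= 1
        assert h_m >= 0
        assert i_m >= 0

    def test_degenerate_mask_rejected(self):
        gray = np.zeros((5, 5), dtype=np.uint8)
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        with pytest.raises(ValueError):
            glcm_features(gray, mask)


class TestColorFeatures:
    def test_uniform_image(self):
        img = np.tile(np.array([10, 20, 30], dtype=np.uint8), (4, 4, 1))
        assert color_features(img, np.ones((4, 4), bool)) == pytest.approx((10, 20, 30))

    def test_half_and_half_mean(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[1] = (200, 100, 50)
        assert color_features(img, np.ones((2, 2), bool)) == pytest.approx((100, 50, 25))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            color_features(np.zeros((2, 2, 3), np.uint8), np.zeros((2, 2), bool))


class TestFeatureVector:
    def test_arity_and_determinism(self):
        frame = posture_template(2).base_map
        a = extract_feature_vector(frame)
        b = extract_feature_vector(frame)
        assert a.shape == (19,)
        assert len(FEATURE_NAMES) == 19
        np.testing.assert_array_equal(a, b)

    def test_lean_posture_differs_from_upright(self):
        v1 = extract_feature_vector(posture_template(1).base_map)
        v5 = extract_feature_vector(posture_template(5).base_map)
        # geometric features respond to the changed contact shape
        assert not np.allclose(v1[:3], v5[:3], rtol=1e-3)


class TestFeatureScaler:
    def test_column_division(self):
        X = np.array([[2.0], [-4.0], [1.0]])
        scaler = FeatureScaler.fit(X)
        np.testing.assert_allclose(scaler.transform(X).ravel(), [0.5, -1.0, 0.25])

    def test_zero_column_passthrough(self):
        X = np.zeros((3, 2))
        X[:, 1] = [1.0, 2.0, -3.0]
        scaler = FeatureScaler.fit(X)
        out = scaler.transform(X)
        np.testing.assert_array_equal(out[:, 0], 0.0)

    def test_fitting_set_maps_into_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 10, (50, 19))
        out = FeatureScaler.fit(X).transform(X)
        assert np.all(np.abs(out) <= 1.0 + 1e-12)
        # the max-|q| row maps to exactly +-1
        assert np.all(np.isclose(np.abs(out), 1.0).any(axis=0))
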