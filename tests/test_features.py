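import numpy as np
import pytest

from nirsbci.features import (
    MOMENT_ORDERS,
    FeatureError,
    combined_features,
    interpolate_topography,
    tchebichef_moments,
    tchebichef_polynomials,
    temporal_features,
    window_slopes,
)

from conftest import make_epoch


def gram_schmidt_moments(image, max_order=4):
    """Brute-force oracle: explicit Gram-Schmidt orthonormal polynomials and
    a double sum over all pixels."""

    def onb(N):
        basis = []
        for p in range(max_order + 1):
            v = np.arange(N, dtype=float) ** p
            for b in basis:
                v = v - (v @ b) * b
            basis.append(v / np.linalg.norm(v))
        return basis

    rows, cols = image.shape
    tr, tc = onb(rows), onb(cols)
    out = []
    for p, q in MOMENT_ORDERS:
        acc = 0.0
        for x in range(rows):
            for y in range(cols):
                acc += tr[p][x] * tc[q][y] * image[x, y]
        out.append(acc)
    return np.array(out)


class TestTemporalFeatures:
    def test_length_108_and_unique_names(self):
        fv = temporal_features(make_epoch(np.zeros((9, 3, 625))))
        assert len(fv.values) == 108
        assert len(set(fv.names)) == 108

    def test_constant_epoch_gives_zero_slopes(self):
        fv = temporal_features(make_epoch(np.full((9, 3, 625), 3.7)))
        np.testing.assert_allclose(fv.values, 0.0, atol=1e-12)

    def test_full_ramp_slope_equals_total_rise_in_every_window(self):
        # rising R uM over 20 s: each window's normalized-time slope is the
        # rise across that window, i.e. R * (w/20)
        R = 2.0
        n = 625
        ramp = np.linspace(0, R, n)
        data = np.tile(ramp, (9, 3, 1))
        fv = temporal_features(make_epoch(data))
        slopes = fv.values.reshape(4, 3, 9)
        for wi, w in enumerate((5, 10, 15, 20)):
            np.testing.assert_allclose(slopes[wi], R * w / 20.0, rtol=1e-2)

    def test_offset_invariance_and_homogeneity(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(9, 3, 625))
        base = temporal_features(make_epoch(data)).values
        shifted = temporal_features(make_epoch(data + 11.0)).values
        scaled = temporal_features(make_epoch(3.0 * data)).values
        np.testing.assert_allclose(shifted, base, atol=1e-9)
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-9)

    def test_nonfinite_epoch_rejected(self):
        data = np.zeros((9, 3, 625))
        data[0, 0, 0] = np.nan
        with pytest.raises(FeatureError):
            temporal_features(make_epoch(data))


class TestInterpolation:
    def test_constant_field_reproduced_on_mask(self, grid, channel_coords):
        img = interpolate_topography(np.full(9, 4.2), grid, channel_coords)
        np.testing.assert_allclose(img[grid.mask], 4.2, rtol=1e-5)
        assert np.all(img[~grid.mask] == 0.0)

    def test_interpolant_exact_at_channel_pixels(self, grid, channel_coords):
        from scipy.interpolate import CloughTocher2DInterpolator

        vals = np.arange(9.0)
        interp = CloughTocher2DInterpolator(channel_coords[:, ::-1], vals)
        np.testing.assert_allclose(interp(channel_coords[:, ::-1]), vals,
                                   atol=1e-9)

    def test_linear_field_reproduced(self, grid, channel_coords):
        rows, cols = channel_coords[:, 0], channel_coords[:, 1]
        field = 0.4 * cols - 0.9 * rows + 1.0
        img = interpolate_topography(field, grid, channel_coords)
        rr, cc = np.nonzero(grid.mask)
        expected = 0.4 * cc - 0.9 * rr + 1.0
        np.testing.assert_allclose(img[rr, cc], expected, atol=1e-6)

    def test_nonfinite_input_rejected(self, grid, channel_coords):
        with pytest.raises(FeatureError):
            interpolate_topography(np.array([np.nan] + [0.0] * 8), grid,
                                   channel_coords)


class TestTchebichefMoments:
    def test_returns_15_moments(self):
        assert len(tchebichef_moments(np.zeros((21, 61)))) == 15
        assert len(MOMENT_ORDERS) == 15

    def test_polynomials_orthonormal(self):
        for N in (21, 61):
            T = tchebichef_polynomials(N, 4)
            np.testing.assert_allclose(T @ T.T, np.eye(5), atol=1e-12)

    def test_constant_image_only_zeroth_moment(self):
        m = tchebichef_moments(np.full((21, 61), 2.0))
        assert m[0] != 0
        np.testing.assert_allclose(m[1:], 0.0, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(size=(21, 61))
        np.testing.assert_allclose(
            tchebichef_moments(img), gram_schmidt_moments(img), atol=1e-9
        )


class TestSpatialFeatures:
    def test_length_180(self, extractor):
        fv = extractor.spatial_features(make_epoch(np.zeros((9, 3, 625))))
        assert len(fv.values) == 180
        assert len(set(fv.names)) == 180

    def test_constant_in_time_gives_zero_slopes(self, extractor):
        data = np.tile(np.random.default_rng(1).normal(size=(9, 3, 1)), (1, 1, 625))
        fv = extractor.spatial_features(make_epoch(data))
        np.testing.assert_allclose(fv.values, 0.0, atol=1e-9)

    def test_spatially_uniform_ramp_scales_mask_moments(self, extractor):
        # every frame of a spatially uniform ramp is c(t) * (uniform frame),
        # so each moment's slope is the ramp slope times the uniform frame's
        # moment; the trapezoid embedding makes several orders respond
        ramp = np.linspace(0, 1, 625)
        data = np.tile(ramp, (9, 3, 1))
        fv = extractor.spatial_features(make_epoch(data))
        vals = fv.values.reshape(4, 3, 15)
        mask_moments = extractor.channel_to_moments @ np.ones(9)
        np.testing.assert_allclose(
            vals[-1], np.broadcast_to(mask_moments, (3, 15)), atol=1e-8
        )
        assert abs(mask_moments[0]) > 1.0  # the (0,0) moment dominates

    def test_operator_matches_direct_path(self, extractor, grid):
        # the precomputed channel-to-moment operator equals interpolation
        # followed by the moment transform, frame by frame
        rng = np.random.default_rng(5)
        frame = rng.normal(size=9)
        img = interpolate_topography(frame, grid, extractor.channel_coords)
        np.testing.assert_allclose(
            extractor.channel_to_moments @ frame,
            tchebichef_moments(img), atol=1e-9,
        )


class TestCombinedFeatures:
    def test_concatenation_is_288_temporal_first(self, extractor):
        ep = make_epoch(np.random.default_rng(2).normal(size=(9, 3, 625)))
        t = temporal_features(ep)
        s = extractor.spatial_features(ep)
        c = combined_features(t, s)
        assert len(c.values) == 288
        assert c.names[: len(t.names)] == t.names
        assert set(t.names).isdisjoint(s.names)
        np.testing.assert_array_equal(c.values[:108], t.values)

    def test_mismatched_epochs_rejected(self, extractor):
        rng = np.random.default_rng(3)
        ep1 = make_epoch(rng.normal(size=(9, 3, 625)))
        ep2 = make_epoch(rng.normal(size=(9, 3, 625)))
        ep2.interval = 7
        t = temporal_features(ep1)
        s = extractor.spatial_features(ep2)
        with pytest.raises(FeatureError, match="different epochs"):
            combined_features(t, s)


def test_window_slopes_closed_form():
    # y = a*t_norm + b on one window: slope must be exactly a
    n = 625
    t = np.linspace(0, 1, n)
    series = 2.5 * t - 1.0
    slopes = window_slopes(series, fs=31.25)
    assert slopes[-1] == pytest.approx(2.5, rel=1e-9)
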