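"""GLGCM construction, descriptors and temperature correlation."""

import warnings

import numpy as np
import pytest
from scipy import stats

from echotherm.datatypes import FeatureSeries, TemperatureTrace, ValidationError
from echotherm.glgcm import (
    GLGCMatrix,
    build_glgcm,
    compute_features,
    extract_feature_series,
    gradient_image,
    gray_temperature_grad,
    pearson_rank,
    quantize_pair,
)


def naive_glgcm(F, G, N, M):
    """Exhaustive double-loop pair counter (independent oracle)."""
    h = np.zeros((N, M), dtype=int)
    for i in range(F.shape[0]):
        for j in range(F.shape[1]):
            h[F[i, j], G[i, j]] += 1
    return h


def sobel_magnitude_oracle(img):
    """Direct kernel application with replicate padding."""
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
    pad = np.pad(img.astype(float), 1, mode="edge")
    gx = np.zeros_like(img, dtype=float)
    gy = np.zeros_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            window = pad[i : i + 3, j : j + 3]
            gx[i, j] = (window * kx).sum()
            gy[i, j] = (window * kx.T).sum()
    return np.hypot(gx, gy)


class TestGradientImage:
    def test_constant_image_has_zero_gradient(self):
        assert np.all(gradient_image(np.full((5, 5), 9.0)) == 0)

    def test_vertical_step_edge_uniform_along_edge(self):
        img = np.zeros((6, 6))
        img[:, 3:] = 255.0
        g = gradient_image(img)
        interior = g[1:-1, 3]
        assert np.all(interior > 0)
        assert np.allclose(interior, interior[0])

    def test_matches_hand_applied_kernels(self, rng):
        img = rng.integers(0, 256, size=(7, 7)).astype(float)
        np.testing.assert_allclose(
            gradient_image(img), sobel_magnitude_oracle(img), atol=1e-9
        )

    def test_too_small_frame_rejected(self):
        with pytest.raises(ValidationError):
            gradient_image(np.zeros((2, 5)))


class TestQuantizePair:
    def test_constant_image_maps_to_level_zero(self):
        f = np.full((4, 4), 7.0)
        q = quantize_pair(f, np.zeros((4, 4)), N=8, M=8)
        assert np.all(q.F == 0) and np.all(q.G == 0)

    def test_extremes_map_to_end_bins(self):
        f = np.array([[0.0, 255.0]])
        q = quantize_pair(f, np.zeros((1, 2)), N=2, M=2)
        np.testing.assert_array_equal(q.F, [[0, 1]])

    def test_ramp_fills_bins_evenly(self):
        f = np.arange(256, dtype=float).reshape(16, 16)
        q = quantize_pair(f, np.zeros((16, 16)), N=4, M=2)
        counts = np.bincount(q.F.ravel(), minlength=4)
        np.testing.assert_array_equal(counts, [64, 64, 64, 64])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            quantize_pair(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_recorded_extrema(self):
        f = np.array([[1.0, 5.0]])
        g = np.array([[0.0, 10.0]])
        q = quantize_pair(f, g, 4, 4)
        assert (q.f_min, q.f_max, q.g_max) == (1.0, 5.0, 10.0)


class TestBuildGlgcm:
    def test_two_by_two_exhaustive_example(self):
        F = np.array([[0, 0], [1, 1]])
        G = np.array([[0, 1], [0, 1]])
        from echotherm.glgcm import QuantizedImagePair

        q = QuantizedImagePair(F, G, 2, 2, 0, 1, 1)
        glg = build_glgcm(q)
        np.testing.assert_array_equal(glg.h, np.ones((2, 2)))
        np.testing.assert_allclose(glg.H, 0.25)

    def test_constant_input_single_cell(self):
        from echotherm.glgcm import QuantizedImagePair

        q = QuantizedImagePair(
            np.zeros((4, 4), int), np.zeros((4, 4), int), 3, 3, 0, 0, 0
        )
        glg = build_glgcm(q)
        assert glg.h[0, 0] == 16
        assert glg.H[0, 0] == 1.0

    @pytest.mark.parametrize("levels", [8, 16])
    def test_matches_naive_pair_counter(self, rng, levels):
        """100 random 8-bit images: exact equality with the double loop."""
        for _ in range(100):
            img = rng.integers(0, 256, size=(16, 16)).astype(float)
            q = quantize_pair(img, gradient_image(img), N=levels, M=levels)
            glg = build_glgcm(q)
            np.testing.assert_array_equal(
                glg.h, naive_glgcm(q.F, q.G, levels, levels)
            )
            assert glg.h.sum() == 256  # every pixel in exactly one cell
            assert abs(glg.H.sum() - 1.0) < 1e-12


class TestComputeFeatures:
    def test_uniform_h_worked_example(self):
        """Hand-checkable uniform 2x2 matrix: all five core descriptors."""
        H = np.full((2, 2), 0.25)
        glg = GLGCMatrix(h=np.ones((2, 2)), H=H, N=2, M=2)
        feats = compute_features(glg)
        assert feats["average_gray_level"] == pytest.approx(0.5, abs=1e-9)
        assert feats["gray_level_entropy"] == pytest.approx(np.log(2), abs=1e-9)
        assert feats["mixture_entropy"] == pytest.approx(np.log(4), abs=1e-9)
        assert feats["inertia"] == pytest.approx(0.5, abs=1e-9)
        assert feats["inverse_difference_moment"] == pytest.approx(0.75, abs=1e-9)

    def test_concentrated_h_has_zero_entropies(self):
        H = np.zeros((3, 3))
        H[1, 2] = 1.0
        glg = GLGCMatrix(h=H * 9, H=H, N=3, M=3)
        feats = compute_features(glg)
        assert feats["gray_level_entropy"] == 0.0
        assert feats["mixture_entropy"] == 0.0

    def test_unnormalized_h_rejected(self):
        glg = GLGCMatrix(h=np.ones((2, 2)), H=np.ones((2, 2)), N=2, M=2)
        with pytest.raises(ValidationError):
            compute_features(glg)

    def test_descriptors_invariant_to_count_scaling(self, rng):
        """Tiling the image multiplies all counts; H and descriptors do not move."""
        img = rng.integers(0, 256, size=(8, 8)).astype(float)
        grad = gradient_image(img)
        q1 = quantize_pair(img, grad, 8, 8)
        big = np.tile(img, (2, 2))
        # reuse the same quantisation levels by passing the small image's extrema
        q2 = quantize_pair(
            big, np.tile(grad, (2, 2)), 8, 8,
            f_range=(q1.f_min, q1.f_max), g_max=q1.g_max,
        )
        f1 = compute_features(build_glgcm(q1), all_descriptors=True)
        f2 = compute_features(build_glgcm(q2), all_descriptors=True)
        assert build_glgcm(q2).h.sum() == 4 * build_glgcm(q1).h.sum()
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12), name

    def test_full_descriptor_set_is_fifteen(self, rng):
        img = rng.integers(0, 256, size=(8, 8)).astype(float)
        q = quantize_pair(img, gradient_image(img), 8, 8)
        feats = compute_features(build_glgcm(q), all_descriptors=True)
        assert len(feats) == 15
        assert all(np.isfinite(v) for v in feats.values())


class TestGrayTemperatureGrad:
    def test_constant_rates_give_constant_ratio(self):
        t = np.arange(20.0)
        temps = 25 + 1.0 * t
        avgl = 100 + 0.5 * t
        out = gray_temperature_grad(avgl, temps, lag=5)
        np.testing.assert_allclose(out, 2.0)
        assert len(out) == 20

    def test_degenerate_denominator_carries_previous(self):
        temps = np.arange(10.0)
        avgl = np.full(10, 50.0)
        out = gray_temperature_grad(avgl, temps, lag=5)
        np.testing.assert_array_equal(out, 0.0)  # carried from series start

    def test_lag_zero_rejected(self):
        with pytest.raises(ValidationError):
            gray_temperature_grad(np.arange(10.0), np.arange(10.0), lag=0)

    def test_series_shorter_than_lag_rejected(self):
        with pytest.raises(ValidationError):
            gray_temperature_grad(np.arange(4.0), np.arange(4.0), lag=5)


class TestPearsonRank:
    def _series(self, x):
        times = np.arange(len(x), dtype=float)
        return FeatureSeries(times, {"x": np.asarray(x, float)})

    def test_perfect_linearity(self):
        temps = np.array([25.0, 30.0, 40.0, 55.0])
        trace = TemperatureTrace(np.arange(4.0), temps)
        up = pearson_rank(self._series(2 * temps + 1), trace)
        assert up.entries[0][1] == pytest.approx(1.0, abs=1e-12)
        down = pearson_rank(self._series(-temps), trace)
        assert down.entries[0][1] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_three_points(self):
        trace = TemperatureTrace(np.arange(3.0), np.array([1.0, 2.0, 4.0]))
        rank = pearson_rank(self._series([1.0, 2.0, 3.0]), trace)
        assert rank.entries[0][1] == pytest.approx(0.981981, abs=1e-6)
        # independent check against scipy
        assert rank.entries[0][1] == pytest.approx(
            stats.pearsonr([1, 2, 3], [1, 2, 4]).statistic, abs=1e-12
        )

    def test_zero_variance_channel_flagged(self):
        trace = TemperatureTrace(np.arange(4.0), np.array([1.0, 2.0, 3.0, 4.0]))
        fs = FeatureSeries(
            np.arange(4.0),
            {"flat": np.full(4, 3.0), "good": np.arange(4.0)},
        )
        with pytest.warns(RuntimeWarning, match="zero variance"):
            rank = pearson_rank(fs, trace)
        assert "flat" in rank.degenerate
        assert dict(rank.entries)["flat"] == 0.0

    def test_too_few_samples_rejected(self):
        trace = TemperatureTrace(np.arange(2.0), np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            pearson_rank(self._series([1.0, 2.0]), trace)


class TestExtractFeatureSeries:
    def test_length_mismatch_rejected(self, rng):
        patches = rng.integers(0, 256, size=(3, 8, 8)).astype(float)
        trace = TemperatureTrace(np.arange(5.0), np.full(5, 25.0))
        with pytest.raises(ValidationError):
            extract_feature_series(patches, trace)

    def test_channels_and_alignment(self, tiny_dataset):
        fs = tiny_dataset.features[0]
        assert fs.temps is not None and len(fs) == len(fs.temps)
        for name in (
            "average_gray_level", "gray_level_entropy", "gray_temperature_grad",
            "mixture_entropy", "inertia", "inverse_difference_moment",
        ):
            assert name in fs.channels
            assert np.isfinite(fs.channels[name]).all()

    def test_avgl_tops_the_feature_ranking(self, tiny_dataset):
        """Ranking logic: AVGL carries the strongest temperature correlation
        (the noiseless full-length r > 0.95 bound is checked separately)."""
        fs = tiny_dataset.features[0]
        trace = TemperatureTrace(fs.times, fs.temps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rank = pearson_rank(fs, trace)
        assert rank.entries[0][0] == "average_gray_level"
        assert rank.entries[0][1] > 0.9
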