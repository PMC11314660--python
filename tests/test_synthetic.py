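"""Synthetic heating-experiment generator: contracts and ground truth."""

import numpy as np
import pytest

from echotherm.datatypes import ValidationError
from echotherm.synthetic import (
    HeatingModel,
    TextureModel,
    draw_experiment_models,
    make_experiment_set,
    simulate_frames,
    simulate_trace,
)

# sub-periods compatible with the short heating runs used in frame-level
# tests (each period must span >= 2 s and <= duration/2)
SHORT_PERIODS = ((4.0, 1.0), (8.0, 0.5))


class TestSimulateTrace:
    def test_closed_form_values(self):
        """T(t) = T0 + (Tmax-T0)(1 - exp(-t/tau)) at t = 0, 120 and late."""
        model = HeatingModel(T0=25, Tmax=65, tau=120, duration=480)
        trace = simulate_trace(model, noise_sd=0.0)
        assert trace.temps[0] == pytest.approx(25.0)
        assert trace.temps[120] == pytest.approx(25 + 40 * (1 - np.exp(-1)))
        assert trace.temps[120] == pytest.approx(50.2848, abs=1e-4)
        # saturates toward the plateau
        long = simulate_trace(HeatingModel(tau=120, duration=12000), 0.0)
        assert long.temps[-1] == pytest.approx(65.0, abs=1e-6)

    def test_sample_count_and_monotonicity(self):
        model = HeatingModel(duration=480, sample_rate=1)
        trace = simulate_trace(model, noise_sd=0.0)
        assert len(trace) == 481
        assert np.all(np.diff(trace.temps) >= 0)

    def test_determinism_and_noise(self):
        model = HeatingModel()
        a = simulate_trace(model, noise_sd=0.3, seed=5)
        b = simulate_trace(model, noise_sd=0.3, seed=5)
        np.testing.assert_array_equal(a.temps, b.temps)
        c = simulate_trace(model, noise_sd=0.3, seed=6)
        assert not np.array_equal(a.temps, c.temps)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(T0=70), dict(tau=-1), dict(duration=0), dict(sample_rate=0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            HeatingModel(**kwargs)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            simulate_trace(HeatingModel(), noise_sd=-0.1)


class TestSimulateFrames:
    def test_degenerate_field_is_flat(self):
        """No coupling, no modulation, no speckle, no pattern -> base_mean."""
        trace = simulate_trace(HeatingModel(duration=10), 0.0)
        tex = TextureModel(
            avgl_slope=0.0, sub_periods=(), speckle_scale=0.0,
            pattern_amplitude=0.0, roi_size=16, frame_rate=10,
        )
        seq = simulate_frames(trace, tex, seed=0)
        assert np.all(seq.frames == 120)
        assert len(seq) == 100

    def test_linear_temperature_coupling(self):
        """slope 0.5 x 40 °C rise -> 20 gray levels between first and last frame."""
        trace = simulate_trace(HeatingModel(duration=480), 0.0)
        # linear ramp trace isolates the coupling from the exponential shape
        from echotherm.datatypes import TemperatureTrace

        ramp = TemperatureTrace(trace.times, np.linspace(25, 65, len(trace)))
        tex = TextureModel(
            avgl_slope=0.5, sub_periods=(), speckle_scale=0.0,
            pattern_amplitude=0.0, roi_size=16,
        )
        seq = simulate_frames(ramp, tex, seed=0)
        first = seq.frames[0].mean()
        last = seq.frames[-1].mean()
        assert last - first == pytest.approx(20.0, abs=0.01)

    def test_bit_identical_under_fixed_seed(self):
        trace = simulate_trace(HeatingModel(duration=20), 0.0)
        tex = TextureModel(roi_size=16, frame_rate=10, sub_periods=SHORT_PERIODS)
        a = simulate_frames(trace, tex, seed=3)
        b = simulate_frames(trace, tex, seed=3)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_pixels_are_8bit(self):
        trace = simulate_trace(HeatingModel(duration=20), 0.0)
        tex = TextureModel(
            base_mean=240.0, roi_size=16, frame_rate=10, sub_periods=SHORT_PERIODS
        )
        seq = simulate_frames(trace, tex, seed=1)
        assert seq.frames.dtype == np.uint8

    def test_small_roi_rejected(self):
        trace = simulate_trace(HeatingModel(duration=20), 0.0)
        with pytest.raises(ValidationError):
            simulate_frames(trace, TextureModel(roi_size=4), seed=0)

    def test_frame_count_matches_span(self):
        trace = simulate_trace(HeatingModel(duration=30), 0.0)
        tex = TextureModel(roi_size=16, frame_rate=10, sub_periods=SHORT_PERIODS)
        assert len(simulate_frames(trace, tex, seed=0)) == 300


class TestExperimentSet:
    def test_single_experiment(self):
        out = make_experiment_set(
            1, HeatingModel(duration=20),
            TextureModel(roi_size=16, frame_rate=10, sub_periods=SHORT_PERIODS),
            seed=0,
        )
        assert len(out) == 1
        assert out[0].injected_periods  # ground truth recorded

    def test_same_seed_identical(self):
        kwargs = dict(
            heating=HeatingModel(duration=20),
            tex=TextureModel(roi_size=16, frame_rate=10, sub_periods=SHORT_PERIODS),
            seed=11,
        )
        a = make_experiment_set(2, **kwargs)
        b = make_experiment_set(2, **kwargs)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.frames.frames, eb.frames.frames)
            np.testing.assert_array_equal(ea.trace.temps, eb.trace.temps)

    def test_thirty_jittered_traces_are_distinct(self):
        """Default jitter must produce pairwise-distinct heating curves."""
        models = draw_experiment_models(30, seed=0)
        traces = [
            simulate_trace(h, noise_sd=0.0).temps for h, _, _ in models
        ]
        for i in range(30):
            for j in range(i + 1, 30):
                assert np.abs(traces[i] - traces[j]).max() > 0

    def test_jitter_preserves_sub_period_values(self):
        base = TextureModel()
        for _, tex, _ in draw_experiment_models(5, tex=base, seed=0):
            assert [p for p, _ in tex.sub_periods] == [
                p for p, _ in base.sub_periods
            ]


class TestSpectralGroundTruth:
    def test_injected_periods_are_local_spectrum_maxima(self):
        """After removing the heating trend, the noiseless mean-gray series
        has DFT local maxima exactly at the injected frequency indices."""
        from scipy import signal

        heating = HeatingModel()  # 480 s
        tex = TextureModel(speckle_scale=0.0, roi_size=16)
        trace = simulate_trace(heating, 0.0)
        seq = simulate_frames(trace, tex, seed=0)
        # per-second mean gray level (one fused value per trace sample)
        block = int(tex.frame_rate)
        n = len(seq) // block
        avgl = (
            seq.frames[: n * block]
            .reshape(n, block, -1)
            .mean(axis=(1, 2))
        )
        spectrum = np.abs(np.fft.rfft(signal.detrend(avgl)))
        for period in (6.0, 20.0, 48.0):
            f = int(round(len(avgl) / period))
            assert spectrum[f] > spectrum[f - 1]
            assert spectrum[f] > spectrum[f + 1]

    def test_noiseless_avgl_tracks_temperature(self):
        """AVGL-temperature Pearson r stays near 1 at default modulation."""
        trace = simulate_trace(HeatingModel(), 0.0)
        tex = TextureModel(speckle_scale=0.0, roi_size=16)
        seq = simulate_frames(trace, tex, seed=0)
        block = int(tex.frame_rate)
        n = len(seq) // block
        avgl = seq.frames[: n * block].reshape(n, block, -1).mean(axis=(1, 2))
        temps = trace.temps[:n]
        r = np.corrcoef(avgl, temps)[0, 1]
        assert r > 0.95
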