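"""Model fitting, experiment-level splitting, metrics and persistence."""

import numpy as np
import pytest

from echotherm.datatypes import FeatureSeries, ValidationError
from echotherm.model import (
    Normalizer,
    TemperatureRegression,
    TemperatureRegressionResults,
    TrainConfig,
    TrainingDivergedError,
    sliding_windows,
)
from echotherm.network import ModelConfig
from echotherm.train import baseline_lstm, evaluate, split_experiments, split_indices


class TestSplit:
    def test_seven_three_rounding(self):
        tr, te = split_indices(40, 0.7, seed=0)
        assert len(tr) == 28 and len(te) == 12

    def test_two_experiments_get_one_each(self):
        tr, te = split_indices(2, 0.7, seed=0)
        assert len(tr) == 1 and len(te) == 1

    def test_deterministic_under_seed(self):
        a = split_indices(17, 0.7, seed=9)
        b = split_indices(17, 0.7, seed=9)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_no_experiment_in_both_sides(self):
        tr, te = split_indices(23, 0.6, seed=4)
        assert set(tr).isdisjoint(te)
        assert sorted(set(tr) | set(te)) == list(range(23))

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            split_indices(1, 0.7, seed=0)

    def test_split_experiments_returns_objects(self, tiny_dataset):
        tr, te = split_experiments(tiny_dataset.features, 0.7, seed=0)
        assert len(tr) + len(te) == len(tiny_dataset.features)


class TestWindowsAndNormalizer:
    def test_tail_window_covers_series_end(self):
        x = np.arange(20.0)[:, None]
        w, t, starts = sliding_windows(x, np.arange(20.0), length=8, stride=6)
        assert starts[-1] == 12  # 20 - 8
        assert w.shape == (3, 8, 1)

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(ValidationError):
            sliding_windows(np.zeros((5, 2)), np.zeros(5), length=8, stride=1)

    def test_normalizer_round_trip(self, rng):
        xs = [rng.normal(size=(30, 4)) * 3 + 7]
        ys = [rng.normal(size=30) * 11 + 40]
        norm = Normalizer.fit(xs, ys)
        np.testing.assert_allclose(
            norm.inverse_y(norm.transform_y(ys[0])), ys[0], atol=1e-12
        )
        z = norm.transform_x(xs[0])
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)


class TestTrainConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValidationError):
            TrainConfig(split_ratio=1.2)
        with pytest.raises(ValidationError):
            TrainConfig(epochs=0)
        with pytest.raises(ValidationError):
            TrainConfig(loss="mae")


class TestFit:
    def test_loss_history_recorded_and_decreasing(self, tiny_results):
        history = tiny_results.loss_history
        assert len(history) == 3
        assert history[-1] <= history[0]

    def test_summary_mentions_key_quantities(self, tiny_results):
        text = tiny_results.summary()
        assert "Trainable parameters" in text
        assert "average_gray_level" in text
        assert "temporal" in text

    def test_gray_temperature_grad_excluded_by_default(self, tiny_results):
        assert "gray_temperature_grad" not in tiny_results.channels

    def test_seeded_fit_reproducible(self, tiny_split):
        """Identical config + seed give identical loss history and weights."""
        train_set, _ = tiny_split
        tc = TrainConfig(epochs=2, seed=3, train_stride=24)
        a = TemperatureRegression(train_set).fit(tc)
        b = TemperatureRegression(train_set).fit(tc)
        assert a.loss_history == b.loss_history
        for pa, pb in zip(a.net.parameters(), b.net.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_raises(self, tiny_split):
        train_set, _ = tiny_split
        # an absurd learning rate overflows float64 within a few steps
        tc = TrainConfig(epochs=4, seed=0, lr=1e200, train_stride=24)
        with pytest.raises(TrainingDivergedError):
            TemperatureRegression(train_set).fit(tc)

    def test_missing_channel_rejected(self, tiny_split):
        train_set, _ = tiny_split
        with pytest.raises(ValidationError, match="lacks channels"):
            TemperatureRegression(train_set, channels=("no_such_channel",))

    def test_from_dataframe_round_trip(self, tiny_dataset):
        import pandas as pd

        frames = []
        for i, fs in enumerate(tiny_dataset.features[:2]):
            df = fs.to_dataframe()
            df["experiment_id"] = i
            frames.append(df)
        model = TemperatureRegression.from_dataframe(pd.concat(frames))
        assert len(model.experiments) == 2
        assert len(model.experiments[0]) == len(tiny_dataset.features[0])


class TestPredictEvaluate:
    def test_prediction_covers_every_step(self, tiny_results, tiny_split):
        _, test_set = tiny_split
        pred = tiny_results.predict(test_set[0])
        assert pred.shape == test_set[0].temps.shape
        assert np.isfinite(pred).all()

    def test_metric_identities(self, tiny_results, tiny_split):
        _, test_set = tiny_split
        report = evaluate(tiny_results, test_set)
        assert report.rmse == pytest.approx(np.sqrt(report.mse), abs=1e-9)
        assert report.mae <= report.rmse + 1e-12
        assert report.n_steps == sum(len(fs) for fs in test_set)
        assert report.per_band  # band breakdown present

    def test_hand_computed_metrics_with_stub_predictor(self):
        """predictions == targets -> 0; +1 bias -> 1/1/1; (+1,-2) -> 2.5/1.5."""

        class Stub:
            def __init__(self, offset):
                self.offset = offset

            def predict(self, fs, stride=None):
                return fs.temps + self.offset

        times = np.arange(2.0)
        fs = FeatureSeries(times, {"x": np.zeros(2)}, temps=np.array([30.0, 40.0]))
        exact = evaluate(Stub(np.zeros(2)), [fs])
        assert (exact.mse, exact.rmse, exact.mae) == (0.0, 0.0, 0.0)
        biased = evaluate(Stub(np.ones(2)), [fs])
        assert (biased.mse, biased.rmse, biased.mae) == (1.0, 1.0, 1.0)
        mixed = evaluate(Stub(np.array([1.0, -2.0])), [fs])
        assert mixed.mse == pytest.approx(2.5)
        assert mixed.mae == pytest.approx(1.5)

    def test_empty_test_set_rejected(self, tiny_results):
        with pytest.raises(ValidationError):
            evaluate(tiny_results, [])


class TestPersistence:
    def test_save_load_round_trip(self, tiny_results, tiny_split, tmp_path):
        _, test_set = tiny_split
        prefix = tmp_path / "ckpt"
        tiny_results.save(prefix)
        loaded = TemperatureRegressionResults.load(prefix)
        np.testing.assert_array_equal(
            tiny_results.predict(test_set[0]), loaded.predict(test_set[0])
        )
        assert loaded.channels == tiny_results.channels
        assert loaded.config == tiny_results.config


class TestBaseline:
    def test_lstm_baseline_trains_and_reports(self, tiny_split):
        train_set, test_set = tiny_split
        tc = TrainConfig(epochs=2, seed=0, train_stride=24)
        report, results = baseline_lstm(
            train_set, test_set, model_cfg=ModelConfig(), train_cfg=tc, seed=0
        )
        assert results.backbone == "lstm"
        assert np.isfinite(report.mse)
        assert results.n_parameters >= 2000
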