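"""Model / Results objects for temperature regression.

`TemperatureRegression` is built from a list of per-experiment feature series
(each aligned with its measured temperature trace); `fit()` trains the
temporal network (or the recurrent baseline) and returns a
`TemperatureRegressionResults` carrying the fitted weights, normalisation
statistics, loss history and evaluation / prediction / persistence methods.

Training follows the usual sequence-to-sequence regime: per-channel z-scoring
with statistics of the training experiments, sliding windows over each
experiment, Adam on the mean squared error of the standardised temperatures,
optional early stopping on a held-out fold of training experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_MODEL_CHANNELS, FeatureSeries, ValidationError
from .network import (
    LSTMRegressor,
    ModelConfig,
    TemperatureNet,
    lstm_hidden_for_budget,
)
from .nn import Adam, Tensor

__all__ = [
    "TrainConfig",
    "TrainingDivergedError",
    "TemperatureRegression",
    "TemperatureRegressionResults",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    Defaults: Adam, learning rate 1e-3, weight decay 1e-5, 1000 epochs, MSE
    loss, 7:3 experiment-level train/test split.  ``train_stride`` /
    ``eval_stride`` control how densely sliding windows sample each
    experiment; predictions of overlapping evaluation windows are averaged.
    """

    lr: float = 0.001
    weight_decay: float = 1e-5
    epochs: int = 1000
    split_ratio: float = 0.7
    batch_size: int = 32
    seed: int = 0
    loss: str = "mse"
    early_stopping: bool = False
    patience: int = 50
    val_fraction: float = 0.15
    train_stride: int = 12
    eval_stride: int = 48

    def __post_init__(self):
        if not 0 < self.split_ratio < 1:
            raise ValidationError("split_ratio must lie in (0, 1)")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValidationError("only the mean-squared-error loss is supported")


@dataclass
class Normalizer:
    """Per-channel z-scoring of features and the temperature target."""

    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float

    @classmethod
    def fit(cls, xs: list[np.ndarray], ys: list[np.ndarray]) -> "Normalizer":
        x = np.concatenate(xs, axis=0)
        y = np.concatenate(ys)
        x_std = x.std(axis=0)
        x_std[x_std == 0] = 1.0
        y_std = y.std() or 1.0
        return cls(x.mean(axis=0), x_std, float(y.mean()), float(y_std))

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x_mean) / self.x_std

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_std

    def inverse_y(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean,
            "y_std": self.y_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            np.asarray(d["x_mean"]), np.asarray(d["x_std"]),
            d["y_mean"], d["y_std"],
        )


def sliding_windows(
    x: np.ndarray, y: np.ndarray, length: int, stride: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut (T, C) features into windows; a tail window anchored at T-length is
    always included so every step is covered.  Returns (windows, targets,
    start indices)."""
    T = len(x)
    if T < length:
        raise ValidationError(f"series length {T} shorter than window {length}")
    starts = list(range(0, T - length + 1, stride))
    if starts[-1] != T - length:
        starts.append(T - length)
    w = np.stack([x[s : s + length] for s in starts])
    t = np.stack([y[s : s + length] for s in starts])
    return w, t, np.asarray(starts)


class TemperatureRegression:
    """Temperature-from-texture regression model over heating experiments.

    Parameters
    ----------
    experiments : list of FeatureSeries
        One per heating run, each with ``temps`` attached (the 1 Hz
        thermocouple trace aligned during preprocessing).
    channels : sequence of str
        Feature channels used as network input.  The default excludes
        ``gray_temperature_grad``, which embeds the prediction target.
    config : ModelConfig
        Network hyperparameters; ``n_channels`` must match ``channels``.
    backbone : {"temporal", "lstm"}
        The temporal-informed network, or the recurrent baseline used for
        ordering comparisons.
    """

    def __init__(
        self,
        experiments: list[FeatureSeries],
        channels: tuple[str, ...] = DEFAULT_MODEL_CHANNELS,
        config: ModelConfig | None = None,
        backbone: str = "temporal",
    ):
        if not experiments:
            raise ValidationError("need at least one experiment")
        for i, fs in enumerate(experiments):
            if fs.temps is None:
                raise ValidationError(f"experiment {i} has no temperatures")
            missing = set(channels) - set(fs.channels)
            if missing:
                raise ValidationError(f"experiment {i} lacks channels {missing}")
        if backbone not in ("temporal", "lstm"):
            raise ValidationError("backbone must be 'temporal' or 'lstm'")
        self.experiments = list(experiments)
        self.channels = tuple(channels)
        self.config = config or ModelConfig(n_channels=len(channels))
        if self.config.n_channels != len(channels):
            raise ValidationError(
                f"config.n_channels = {self.config.n_channels} but "
                f"{len(channels)} channels given"
            )
        self.backbone = backbone

    @classmethod
    def from_experiments(cls, experiments, **kwargs) -> "TemperatureRegression":
        return cls(experiments, **kwargs)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        experiment_col: str = "experiment_id",
        **kwargs,
    ) -> "TemperatureRegression":
        """Build from a long-format frame with one row per (experiment, second)."""
        experiments = [
            FeatureSeries.from_dataframe(g.drop(columns=[experiment_col]))
            for _, g in df.groupby(experiment_col, sort=True)
        ]
        return cls(experiments, **kwargs)

    # ------------------------------------------------------------------

    def _build_net(self, seed: int):
        cfg = replace(self.config, seed=seed)
        if self.backbone == "temporal":
            return TemperatureNet(cfg), cfg
        hidden = lstm_hidden_for_budget(
            cfg.n_channels, TemperatureNet(cfg).n_parameters()
        )
        return LSTMRegressor(cfg.n_channels, hidden, seed=seed), cfg

    def fit(self, train_config: TrainConfig | None = None,
            verbose: bool = False) -> "TemperatureRegressionResults":
        tc = train_config or TrainConfig()
        rng = np.random.default_rng(tc.seed)

        xs = [fs.matrix(self.channels) for fs in self.experiments]
        ys = [fs.temps for fs in self.experiments]
        norm = Normalizer.fit(xs, ys)

        n = len(self.experiments)
        idx = np.arange(n)
        val_idx: np.ndarray = np.array([], dtype=int)
        if tc.early_stopping and n >= 3:
            n_val = max(1, int(round(tc.val_fraction * n)))
            val_idx = rng.permutation(n)[:n_val]
        train_idx = np.setdiff1d(idx, val_idx)

        def windows_for(indices, stride):
            ws, ts = [], []
            for i in indices:
                w, t, _ = sliding_windows(
                    norm.transform_x(xs[i]), norm.transform_y(ys[i]),
                    self.config.window_length, stride,
                )
                ws.append(w)
                ts.append(t)
            return np.concatenate(ws), np.concatenate(ts)

        w_train, t_train = windows_for(train_idx, tc.train_stride)
        has_val = len(val_idx) > 0
        if has_val:
            w_val, t_val = windows_for(val_idx, tc.eval_stride)

        net, cfg = self._build_net(tc.seed)
        net.set_rng(rng)
        if hasattr(net, "skip"):
            # two-stage fit: the per-step linear bypass is initialised in
            # closed form (OLS on the training windows), so gradient training
            # starts from the best pointwise-linear model and the period
            # blocks only have to learn the temporal residual
            a = w_train.reshape(-1, w_train.shape[-1])
            a = np.c_[a, np.ones(len(a))]
            sol, *_ = np.linalg.lstsq(a, t_train.ravel(), rcond=None)
            net.skip.weight.data = sol[:-1, None].copy()
            net.skip.bias.data = sol[-1:].copy()
        opt = Adam(net.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)

        loss_history: list[float] = []
        val_history: list[float] = []
        best_val = np.inf
        best_state = None
        best_epoch = 0
        stale = 0
        n_windows = len(w_train)
        for epoch in range(tc.epochs):
            net.set_training(True)
            order = rng.permutation(n_windows)
            losses = []
            for lo in range(0, n_windows, tc.batch_size):
                batch = order[lo : lo + tc.batch_size]
                pred = net(Tensor(w_train[batch]))
                err = pred - Tensor(t_train[batch])
                loss = (err * err).mean()
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            loss_history.append(float(np.mean(losses)))
            if has_val:
                val_loss = float(np.mean((net.predict(w_val) - t_val) ** 2))
                val_history.append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_state = net.state_dict()
                    best_epoch = epoch
                    stale = 0
                else:
                    stale += 1
                    if tc.early_stopping and stale > tc.patience:
                        break
            if verbose:
                msg = f"epoch {epoch:4d}  train {loss_history[-1]:.5f}"
                if has_val:
                    msg += f"  val {val_history[-1]:.5f}"
                print(msg)
        if best_state is not None:
            net.load_state_dict(best_state)
        net.set_training(False)
        return TemperatureRegressionResults(
            model=self,
            net=net,
            config=cfg,
            train_config=tc,
            channels=self.channels,
            normalizer=norm,
            loss_history=loss_history,
            val_history=val_history,
            best_epoch=best_epoch if has_val else len(loss_history) - 1,
            backbone=self.backbone,
        )


class TemperatureRegressionResults:
    """Fitted temperature regression: weights, diagnostics and predictions."""

    def __init__(self, *, model, net, config, train_config, channels,
                 normalizer, loss_history, val_history, best_epoch, backbone):
        self.model = model
        self.net = net
        self.config = config
        self.train_config = train_config
        self.channels = tuple(channels)
        self.normalizer = normalizer
        self.loss_history = loss_history
        self.val_history = val_history
        self.best_epoch = best_epoch
        self.backbone = backbone

    @property
    def n_parameters(self) -> int:
        return self.net.n_parameters()

    @property
    def storage_bytes(self) -> int:
        return 4 * self.n_parameters

    def predict(self, fs: FeatureSeries, stride: int | None = None) -> np.ndarray:
        """Per-second temperature estimates (°C) for one experiment.

        Sliding windows of the configured length are predicted and averaged
        where they overlap.
        """
        stride = stride or self.train_config.eval_stride
        x = self.normalizer.transform_x(fs.matrix(self.channels))
        dummy = np.zeros(len(x))
        windows, _, starts = sliding_windows(
            x, dummy, self.config.window_length, stride
        )
        preds = self.net.predict(windows)
        total = np.zeros(len(x))
        count = np.zeros(len(x))
        L = self.config.window_length
        for row, s in enumerate(starts):
            total[s : s + L] += preds[row]
            count[s : s + L] += 1
        return self.normalizer.inverse_y(total / count)

    def evaluate(self, experiments: list[FeatureSeries], **kwargs):
        from .train import evaluate as _evaluate

        return _evaluate(self, experiments, **kwargs)

    def summary(self) -> str:
        """Plain-text summary table in the spirit of statsmodels results."""
        lines = [
            "Temperature Regression Results",
            "=" * 58,
            f"{'Backbone:':<28}{self.backbone}",
            f"{'Input channels:':<28}{len(self.channels)}",
            f"{'Window length:':<28}{self.config.window_length}",
            f"{'k periods:':<28}{self.config.k_periods}",
            f"{'Embedding dim:':<28}{self.config.embed_dim}",
            f"{'Blocks:':<28}{self.config.n_blocks}",
            f"{'Trainable parameters:':<28}{self.n_parameters}",
            f"{'Storage (float32, MB):':<28}{self.storage_bytes / 2**20:.4f}",
            f"{'Training experiments:':<28}"
            f"{len(self.model.experiments) if self.model else 'n/a'}",
            f"{'Epochs run:':<28}{len(self.loss_history)}",
            f"{'Final train MSE (std.):':<28}{self.loss_history[-1]:.5f}",
        ]
        if self.val_history:
            lines.append(
                f"{'Best val MSE (std.):':<28}{min(self.val_history):.5f}"
                f"  (epoch {self.best_epoch})"
            )
        lines.append("=" * 58)
        lines.append("channels: " + ", ".join(self.channels))
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, prefix) -> None:
        """Write ``<prefix>.weights.npy`` plus a ``<prefix>.json`` sidecar
        with the full configuration, channel names and normalisation stats."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        np.save(str(prefix) + ".weights.npy",
                np.array([self.net.state_dict()], dtype=object),
                allow_pickle=True)
        sidecar = {
            "backbone": self.backbone,
            "config": self.config.to_dict(),
            "channels": list(self.channels),
            "normalizer": self.normalizer.to_dict(),
            "train_config": asdict(self.train_config),
            "loss_history": self.loss_history,
            "val_history": self.val_history,
            "best_epoch": self.best_epoch,
            "n_parameters": self.n_parameters,
        }
        if self.backbone == "lstm":
            sidecar["hidden"] = self.net.hidden_size
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, prefix) -> "TemperatureRegressionResults":
        prefix = str(prefix)
        with open(prefix + ".json") as fh:
            sidecar = json.load(fh)
        cfg = ModelConfig(**sidecar["config"])
        if sidecar["backbone"] == "temporal":
            net = TemperatureNet(cfg)
        else:
            net = LSTMRegressor(cfg.n_channels, sidecar["hidden"], seed=cfg.seed)
        state = np.load(prefix + ".weights.npy", allow_pickle=True)[0]
        net.load_state_dict(state)
        net.set_training(False)
        return cls(
            model=None,
            net=net,
            config=cfg,
            train_config=TrainConfig(**sidecar["train_config"]),
            channels=sidecar["channels"],
            normalizer=Normalizer.from_dict(sidecar["normalizer"]),
            loss_history=sidecar["loss_history"],
            val_history=sidecar["val_history"],
            best_epoch=sidecar["best_epoch"],
            backbone=sidecar["backbone"],
        )
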