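"""Experiment-level splitting, evaluation metrics and the recurrent baseline.

The unit of the train/test split is the heating experiment, never the window:
time steps within one heating run are strongly dependent, so window-level
splitting would leak information between the sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import FeatureSeries, ValidationError
from .model import TemperatureRegression, TemperatureRegressionResults, TrainConfig
from .network import ModelConfig

__all__ = [
    "split_indices",
    "split_experiments",
    "train",
    "evaluate",
    "baseline_lstm",
    "EvalReport",
    "DEFAULT_BANDS",
]

#: temperature bands used for the error breakdown (°C): initial transient,
#: mild hyperthermia and thermo-ablation regimes.
DEFAULT_BANDS = ((25.0, 30.0), (30.0, 45.0), (45.0, 65.0))


@dataclass
class EvalReport:
    """Held-out prediction errors: overall, per experiment and per band."""

    mse: float
    rmse: float
    mae: float
    n_steps: int
    per_experiment: list[dict] = field(default_factory=list)
    per_band: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "n_steps": self.n_steps,
            "per_experiment": self.per_experiment,
            "per_band": self.per_band,
        }


def split_indices(n: int, ratio: float = 0.7, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically split ``range(n)``; train size round(ratio*n), but at
    least one experiment on each side."""
    if n < 2:
        raise ValidationError("need at least 2 experiments to split")
    if not 0 < ratio < 1:
        raise ValidationError("ratio must lie in (0, 1)")
    n_train = min(max(int(round(ratio * n)), 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def split_experiments(experiments: list, ratio: float = 0.7, seed: int = 0
                      ) -> tuple[list, list]:
    """Assign whole experiments to train or test (no window leakage)."""
    tr, te = split_indices(len(experiments), ratio, seed)
    return [experiments[i] for i in tr], [experiments[i] for i in te]


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    train_set: list[FeatureSeries],
    channels=None,
    backbone: str = "temporal",
    verbose: bool = False,
) -> TemperatureRegressionResults:
    """Fit a temperature regression on the training experiments."""
    kwargs = {"config": model_cfg, "backbone": backbone}
    if channels is not None:
        kwargs["channels"] = tuple(channels)
    model = TemperatureRegression(train_set, **kwargs)
    return model.fit(train_cfg, verbose=verbose)


def evaluate(
    results: TemperatureRegressionResults,
    test_set: list[FeatureSeries],
    bands: tuple = DEFAULT_BANDS,
    stride: int | None = None,
) -> EvalReport:
    """Metrics over all per-step predictions on held-out experiments."""
    if not test_set:
        raise ValidationError("empty test set")
    all_err = []
    all_true = []
    per_exp = []
    for i, fs in enumerate(test_set):
        if fs.temps is None:
            raise ValidationError(f"test experiment {i} has no temperatures")
        pred = results.predict(fs, stride=stride)
        err = pred - fs.temps
        all_err.append(err)
        all_true.append(fs.temps)
        per_exp.append(
            {
                "experiment": i,
                "n_steps": len(err),
                "mse": float(np.mean(err**2)),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "mae": float(np.mean(np.abs(err))),
            }
        )
    err = np.concatenate(all_err)
    true = np.concatenate(all_true)
    mse = float(np.mean(err**2))
    per_band = {}
    for lo, hi in bands:
        mask = (true >= lo) & (true < hi)
        if mask.any():
            e = err[mask]
            per_band[f"{lo:g}-{hi:g}"] = {
                "n_steps": int(mask.sum()),
                "mse": float(np.mean(e**2)),
                "rmse": float(np.sqrt(np.mean(e**2))),
                "mae": float(np.mean(np.abs(e))),
            }
    return EvalReport(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(err))),
        n_steps=len(err),
        per_experiment=per_exp,
        per_band=per_band,
    )


def baseline_lstm(
    train_set: list[FeatureSeries],
    test_set: list[FeatureSeries],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    channels=None,
) -> tuple[EvalReport, TemperatureRegressionResults]:
    """Train and evaluate the single-layer recurrent baseline.

    The hidden size is chosen as the smallest giving at least as many
    parameters as the primary model, so the comparison is not capacity-bound;
    the same TrainConfig is used.
    """
    model_cfg = model_cfg or ModelConfig(
        n_channels=len(channels) if channels else 5
    )
    train_cfg = train_cfg or TrainConfig()
    if seed is not None:
        from dataclasses import replace

        train_cfg = replace(train_cfg, seed=seed)
    results = train(
        model_cfg, train_cfg, train_set, channels=channels, backbone="lstm"
    )
    return evaluate(results, test_set), results
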