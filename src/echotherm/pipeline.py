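"""Reproducible pipeline: simulate -> preprocess -> features -> train ->
evaluate -> render, driven by a structured YAML config.

Each stage writes under a run-id-scoped directory; a manifest records the
normalised config, its hash, the seed, library versions and a SHA-256
checksum of every file written, so reruns with an identical config are
byte-verifiable.  Simulated image stacks are regenerated in memory from the
recorded seeds rather than written to disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .datatypes import DEFAULT_CHANNELS, DEFAULT_MODEL_CHANNELS
from .datasets import simulate_feature_dataset
from .model import TrainConfig
from .network import ModelConfig
from .render import render_prediction_curves
from .synthetic import DEFAULT_SUB_PERIODS, HeatingModel, TextureModel
from .train import baseline_lstm, evaluate, split_indices, train

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineStageError"]

log = logging.getLogger("echotherm.pipeline")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateSection(_Section):
    n_experiments: int = Field(default=40, ge=1)
    T0: float = 25.0
    Tmax: float = 65.0
    tau: float = Field(default=120.0, gt=0)
    duration: float = Field(default=480.0, gt=0)
    base_mean: float = 120.0
    avgl_slope: float = 0.5
    sub_periods: list[tuple[float, float]] = Field(
        default_factory=lambda: [tuple(p) for p in DEFAULT_SUB_PERIODS]
    )
    speckle_scale: float = Field(default=1.0, ge=0)
    frame_rate: float = Field(default=30.0, gt=0)
    roi_size: int = Field(default=64, ge=8)
    pattern_amplitude: float = 25.0
    trace_noise_sd: float = Field(default=0.05, ge=0)
    jitter: bool = True


class PreprocessSection(_Section):
    kernel: int = Field(default=3, ge=1)


class FeatureSection(_Section):
    gray_levels: int = Field(default=16, ge=2)
    gradient_levels: int = Field(default=16, ge=2)
    lag: int = Field(default=5, ge=1)
    # leakage-documented mode: feed the gray-temperature gradient (which uses
    # measured temperatures) to the model
    use_gray_temperature_grad: bool = False
    all_descriptors: bool = False


class ModelSection(_Section):
    k_periods: int = Field(default=5, ge=1)
    embed_dim: int = Field(default=16, ge=2)
    n_blocks: int = Field(default=2, ge=1)
    n_heads: int = Field(default=2, ge=1)
    local_kernel: int = 3
    branch_split: float = 0.5
    window_length: int = Field(default=96, ge=2)
    dropout: float = Field(default=0.1, ge=0, lt=1)


class TrainSection(_Section):
    lr: float = Field(default=0.001, gt=0)
    weight_decay: float = Field(default=1e-5, ge=0)
    epochs: int = Field(default=1000, ge=1)
    split_ratio: float = Field(default=0.7, gt=0, lt=1)
    batch_size: int = Field(default=32, ge=1)
    early_stopping: bool = False
    patience: int = Field(default=50, ge=1)
    val_fraction: float = 0.15
    train_stride: int = Field(default=12, ge=1)
    eval_stride: int = Field(default=48, ge=1)
    baseline: bool = False


class RenderSection(_Section):
    curves: bool = True


class PipelineConfig(_Section):
    seed: int = 0
    run_id: str = "run"
    out_root: str = "runs"
    simulate: SimulateSection = Field(default_factory=SimulateSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    features: FeatureSection = Field(default_factory=FeatureSection)
    model: ModelSection = Field(default_factory=ModelSection)
    train: TrainSection = Field(default_factory=TrainSection)
    render: RenderSection = Field(default_factory=RenderSection)

    def heating_model(self) -> HeatingModel:
        s = self.simulate
        return HeatingModel(T0=s.T0, Tmax=s.Tmax, tau=s.tau, duration=s.duration)

    def texture_model(self) -> TextureModel:
        s = self.simulate
        return TextureModel(
            base_mean=s.base_mean,
            avgl_slope=s.avgl_slope,
            sub_periods=tuple(tuple(p) for p in s.sub_periods),
            speckle_scale=s.speckle_scale,
            frame_rate=s.frame_rate,
            roi_size=s.roi_size,
            pattern_amplitude=s.pattern_amplitude,
        )

    def channel_names(self) -> tuple[str, ...]:
        if self.features.use_gray_temperature_grad:
            return DEFAULT_CHANNELS
        return DEFAULT_MODEL_CHANNELS

    def model_config_obj(self) -> ModelConfig:
        m = self.model
        return ModelConfig(
            n_channels=len(self.channel_names()),
            k_periods=m.k_periods,
            embed_dim=m.embed_dim,
            n_blocks=m.n_blocks,
            n_heads=m.n_heads,
            local_kernel=m.local_kernel,
            branch_split=m.branch_split,
            window_length=m.window_length,
            dropout=m.dropout,
            seed=self.seed,
        )

    def train_config_obj(self) -> TrainConfig:
        t = self.train
        return TrainConfig(
            lr=t.lr,
            weight_decay=t.weight_decay,
            epochs=t.epochs,
            split_ratio=t.split_ratio,
            batch_size=t.batch_size,
            seed=self.seed,
            early_stopping=t.early_stopping,
            patience=t.patience,
            val_fraction=t.val_fraction,
            train_stride=t.train_stride,
            eval_stride=t.eval_stride,
        )


def validate_config(path_or_dict) -> PipelineConfig:
    """Load and normalise a YAML pipeline config; unknown keys are rejected."""
    if isinstance(path_or_dict, dict):
        return PipelineConfig.model_validate(path_or_dict)
    with open(path_or_dict) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(cfg: PipelineConfig) -> str:
    # out_root is where results land, not what is computed: exclude it so
    # the hash identifies the study, not the deployment location
    blob = json.dumps(
        cfg.model_dump(mode="json", exclude={"out_root"}), sort_keys=True
    ).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(cfg: PipelineConfig, seed: int | None = None) -> Path:
    """Run every stage; returns the run directory.

    A stage failure aborts with the failing stage named; outputs of completed
    stages are preserved.
    """
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    run_dir = Path(cfg.out_root) / cfg.run_id
    run_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    if cfg.features.use_gray_temperature_grad:
        log.warning(
            "leakage mode enabled: the gray-temperature-grad channel feeds "
            "measured temperatures (the prediction target) to the model"
        )

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start (seed %d)", name, cfg.seed)
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - named stage abort
                raise PipelineStageError(name, exc) from exc
            timings[name] = time.perf_counter() - t0
            log.info("stage %s: done in %.1f s", name, timings[name])

        return deco

    state: dict = {}

    @stage("simulate+preprocess+features")
    def _features():
        s = cfg.simulate
        ds = simulate_feature_dataset(
            s.n_experiments,
            heating=cfg.heating_model(),
            tex=cfg.texture_model(),
            seed=cfg.seed,
            trace_noise_sd=s.trace_noise_sd,
            jitter=s.jitter,
            kernel=cfg.preprocess.kernel,
            N=cfg.features.gray_levels,
            M=cfg.features.gradient_levels,
            lag=cfg.features.lag,
            all_descriptors=cfg.features.all_descriptors,
        )
        feat_dir = run_dir / "features"
        feat_dir.mkdir(exist_ok=True)
        for i, fs in enumerate(ds.features):
            path = feat_dir / f"experiment_{i:03d}.csv"
            fs.to_csv(path)
            written.append(path)
        meta = feat_dir / "meta.json"
        meta.write_text(
            json.dumps(
                {
                    "injected_periods": ds.injected_periods,
                    "seeds": ds.seeds,
                    "n_experiments": s.n_experiments,
                },
                indent=2,
                sort_keys=True,
            )
        )
        written.append(meta)
        state["dataset"] = ds

    @stage("train")
    def _train():
        ds = state["dataset"]
        tr_idx, te_idx = split_indices(
            len(ds.features), cfg.train.split_ratio, cfg.seed
        )
        state["split"] = {"train": tr_idx.tolist(), "test": te_idx.tolist()}
        train_set = [ds.features[i] for i in tr_idx]
        state["test_set"] = [ds.features[i] for i in te_idx]
        results = train(
            cfg.model_config_obj(),
            cfg.train_config_obj(),
            train_set,
            channels=cfg.channel_names(),
        )
        state["results"] = results
        train_dir = run_dir / "train"
        train_dir.mkdir(exist_ok=True)
        results.save(train_dir / "model")
        written.extend([train_dir / "model.weights.npy", train_dir / "model.json"])
        split_manifest = train_dir / "split.json"
        split_manifest.write_text(json.dumps(state["split"], sort_keys=True))
        written.append(split_manifest)
        summary = train_dir / "summary.txt"
        summary.write_text(results.summary() + "\n")
        written.append(summary)

    @stage("evaluate")
    def _evaluate():
        report = evaluate(state["results"], state["test_set"])
        state["report"] = report
        eval_dir = run_dir / "eval"
        eval_dir.mkdir(exist_ok=True)
        payload = {
            "metrics": report.to_dict(),
            "split": state["split"],
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
        }
        if cfg.train.baseline:
            base_report, _ = baseline_lstm(
                [state["dataset"].features[i] for i in
                 split_indices(len(state["dataset"].features),
                               cfg.train.split_ratio, cfg.seed)[0]],
                state["test_set"],
                model_cfg=cfg.model_config_obj(),
                train_cfg=cfg.train_config_obj(),
                seed=cfg.seed,
                channels=cfg.channel_names(),
            )
            payload["baseline_lstm"] = base_report.to_dict()
        path = eval_dir / "report.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        written.append(path)

    @stage("render")
    def _render():
        if not cfg.render.curves:
            return
        paths = render_prediction_curves(
            state["results"], state["test_set"], run_dir / "render"
        )
        written.extend(paths)

    import matplotlib
    import pandas
    import scipy

    manifest = {
        "run_id": cfg.run_id,
        "seed": cfg.seed,
        "config": cfg.model_dump(mode="json"),
        "config_hash": _config_hash(cfg),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "matplotlib": matplotlib.__version__,
        },
        "checksums": {
            str(p.relative_to(run_dir)): _sha256(p) for p in written
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return run_dir
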