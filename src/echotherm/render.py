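"""Rendering: predicted-vs-measured curves and 2D pseudocolor temperature maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datatypes import (
    FeatureSeries,
    RoiSpec,
    TemperatureTrace,
    UltrasoundFrameSequence,
    ValidationError,
)
from .glgcm import extract_feature_series
from .model import TemperatureRegressionResults
from .preprocess import extract_roi, mean_filter, align_with_trace, temporal_fuse

__all__ = ["render_prediction_curves", "render_pseudocolor_map"]


def render_prediction_curves(
    results: TemperatureRegressionResults,
    test_set: list[FeatureSeries],
    out_dir,
) -> list[Path]:
    """One PNG per experiment: measured and predicted temperature vs time."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, fs in enumerate(test_set):
        pred = results.predict(fs)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(fs.times, fs.temps, label="measured", lw=1.5)
        ax.plot(fs.times, pred, label="predicted", lw=1.0, ls="--")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("temperature (°C)")
        rmse = float(np.sqrt(np.mean((pred - fs.temps) ** 2)))
        ax.set_title(f"experiment {i}: RMSE {rmse:.3f} °C")
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"prediction_{i:03d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths


def render_pseudocolor_map(
    results: TemperatureRegressionResults,
    seq: UltrasoundFrameSequence,
    trace: TemperatureTrace,
    out_dir,
    roi_size: int = 64,
    grid_stride: int = 16,
    snapshot_times: list[float] | None = None,
    kernel: int = 3,
    N: int = 16,
    M: int = 16,
    lag: int = 5,
) -> list[Path]:
    """Slide the ROI across the fused frames on a stride grid, predict a
    temperature series per tile, and render the tile temperatures at selected
    times on a fixed 25-65 °C color scale with a color bar."""
    rows, cols = seq.shape
    if rows < roi_size or cols < roi_size:
        raise ValidationError("frames smaller than the ROI")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fused = temporal_fuse(seq, target_rate=1.0)
    pairs = align_with_trace(fused, trace)
    filtered = np.stack([mean_filter(frame, kernel) for frame, _ in pairs])
    temps = np.array([t for _, t in pairs])
    aligned = TemperatureTrace(fused.times[: len(pairs)], temps)

    half = roi_size // 2
    centers_r = list(range(half, rows - (roi_size - half) + 1, grid_stride))
    centers_c = list(range(half, cols - (roi_size - half) + 1, grid_stride))
    tile_preds = np.empty((len(centers_r), len(centers_c), len(aligned)))
    for a, cr in enumerate(centers_r):
        for b, cc in enumerate(centers_c):
            patches = extract_roi(filtered, RoiSpec(cr, cc, roi_size))
            fs = extract_feature_series(patches, aligned, N=N, M=M, lag=lag)
            tile_preds[a, b] = results.predict(fs)

    if snapshot_times is None:
        snapshot_times = list(
            np.quantile(aligned.times, [0.0, 0.25, 0.5, 0.75, 1.0])
        )
    paths = []
    for ts in snapshot_times:
        j = int(np.argmin(np.abs(aligned.times - ts)))
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(
            tile_preds[:, :, j], vmin=25.0, vmax=65.0, cmap="jet",
            interpolation="nearest",
        )
        ax.set_title(f"predicted temperature, t = {aligned.times[j]:.0f} s")
        ax.set_xticks(range(len(centers_c)), centers_c)
        ax.set_yticks(range(len(centers_r)), centers_r)
        ax.set_xlabel("tile center col (px)")
        ax.set_ylabel("tile center row (px)")
        fig.colorbar(im, ax=ax, label="°C")
        fig.tight_layout()
        path = out_dir / f"tempmap_t{int(round(aligned.times[j])):04d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
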