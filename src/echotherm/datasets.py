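"""End-to-end dataset construction from the synthetic generator.

Streams each simulated experiment through preprocessing and feature
extraction one at a time, so image stacks never accumulate in memory.  The
parameter draws are identical to :func:`echotherm.synthetic.make_experiment_set`
with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import FeatureSeries, RoiSpec
from .glgcm import extract_feature_series
from .preprocess import preprocess_sequence
from .synthetic import (
    HeatingModel,
    TextureModel,
    draw_experiment_models,
    simulate_frames,
    simulate_trace,
)

__all__ = ["SyntheticDataset", "simulate_feature_dataset"]


@dataclass
class SyntheticDataset:
    """Feature series per experiment plus the generator's ground truth."""

    features: list[FeatureSeries]
    injected_periods: list[list[float]]
    seeds: list[int]


def simulate_feature_dataset(
    n: int,
    heating: HeatingModel = HeatingModel(),
    tex: TextureModel = TextureModel(),
    seed: int = 0,
    trace_noise_sd: float = 0.05,
    jitter: bool = True,
    kernel: int = 3,
    N: int = 16,
    M: int = 16,
    lag: int = 5,
    all_descriptors: bool = False,
) -> SyntheticDataset:
    """Simulate ``n`` heating experiments and extract their feature series."""
    features = []
    injected = []
    seeds = []
    for h, t, child_seed in draw_experiment_models(n, heating, tex, seed, jitter):
        trace = simulate_trace(h, noise_sd=trace_noise_sd, seed=child_seed)
        frames = simulate_frames(trace, t, seed=child_seed + 1)
        roi = RoiSpec(t.roi_size // 2, t.roi_size // 2, t.roi_size)
        patches, aligned = preprocess_sequence(frames, trace, roi, kernel=kernel)
        features.append(
            extract_feature_series(
                patches, aligned, N=N, M=M, lag=lag, all_descriptors=all_descriptors
            )
        )
        injected.append([p for p, _ in t.sub_periods])
        seeds.append(child_seed)
    return SyntheticDataset(features, injected, seeds)
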