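"""Frame ingestion, temporal fusion, speckle smoothing and ROI extraction.

The preprocessing chain mirrors common practice for B-mode texture analysis:
the ~30 fps video is fused (block-averaged) down to the 1 Hz thermocouple
rate, each fused frame is box-filtered to suppress residual speckle, and a
fixed square region of interest around the temperature probe is cut out.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy import ndimage

from .datatypes import (
    RoiSpec,
    TemperatureTrace,
    UltrasoundFrameSequence,
    ValidationError,
)
from . import avi

__all__ = [
    "read_sequence",
    "temporal_fuse",
    "mean_filter",
    "extract_roi",
    "align_with_trace",
    "preprocess_sequence",
]

_FRAME_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}

# ITU-R BT.601 luma weights for color-to-gray conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray8(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3] @ _LUMA
    if img.dtype != np.uint8:
        img = np.clip(np.floor(np.asarray(img, dtype=float) + 0.5), 0, 255)
    return img.astype(np.uint8)


def read_sequence(path, frame_rate: float | None = None) -> UltrasoundFrameSequence:
    """Read an AVI file or a directory of sortable image frames.

    Directories require an explicit ``frame_rate``; AVI containers carry it
    in their headers.  Color frames are converted to 8-bit gray (BT.601 luma).
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES
        )
        if not files:
            raise ValidationError(f"no frames found in {path}")
        if frame_rate is None:
            raise ValidationError(
                "frame_rate is required when reading a frame directory"
            )
        frames = [_to_gray8(iio.imread(p)) for p in files]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise ValidationError(f"inconsistent frame shapes in {path}: {shapes}")
        return UltrasoundFrameSequence(np.stack(frames), frame_rate)
    if path.suffix.lower() == ".avi":
        frames, fps = avi.read_avi(path)
        return UltrasoundFrameSequence(frames, frame_rate or fps)
    raise ValidationError(f"{path}: expected an AVI file or a frame directory")


def temporal_fuse(seq: UltrasoundFrameSequence,
                  target_rate: float) -> UltrasoundFrameSequence:
    """Block-average frames down to ``target_rate`` (usually the 1 Hz trace rate).

    Each output frame is the pixelwise arithmetic mean of one non-overlapping
    block of ``round(frame_rate / target_rate)`` input frames, rounded half-up
    to 8 bits; a trailing partial block is dropped.
    """
    if target_rate <= 0:
        raise ValidationError("target_rate must be positive")
    if target_rate > seq.frame_rate:
        raise ValidationError("target_rate exceeds the sequence frame rate")
    ratio = seq.frame_rate / target_rate
    block = int(round(ratio))
    if abs(ratio - block) >= 0.5 or block < 1:
        raise ValidationError(
            f"frame_rate/target_rate = {ratio:.3f} is not close to an integer"
        )
    n_blocks = len(seq) // block
    if n_blocks == 0:
        raise ValidationError("sequence shorter than one fusion block")
    usable = seq.frames[: n_blocks * block].astype(np.float64)
    fused = usable.reshape(n_blocks, block, *seq.shape).mean(axis=1)
    fused = np.floor(fused + 0.5).astype(np.uint8)
    return UltrasoundFrameSequence(fused, target_rate, t0=seq.t0)


def mean_filter(frame: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Box filter with replicate (edge) padding; returns floats."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValidationError("kernel must be an odd positive integer")
    out = np.asarray(frame, dtype=np.float64)
    if kernel == 1:
        return out.copy()
    return ndimage.uniform_filter(out, size=kernel, mode="nearest")


def extract_roi(frame: np.ndarray, roi: RoiSpec) -> np.ndarray:
    """Cut the half-open ``size x size`` patch centered on the ROI spec."""
    r0, r1, c0, c1 = roi.bounds()
    rows, cols = frame.shape[-2:]
    if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
        raise ValidationError(
            f"ROI rows [{r0},{r1}) cols [{c0},{c1}) out of bounds for "
            f"{rows}x{cols} frame"
        )
    return frame[..., r0:r1, c0:c1].copy()


def align_with_trace(
    seq_1hz: UltrasoundFrameSequence,
    trace: TemperatureTrace,
    tolerance: float = 0.5,
) -> list[tuple[np.ndarray, float]]:
    """Pair fused frames with trace samples by nearest timestamp."""
    if abs(seq_1hz.frame_rate - 1.0) > 1e-6:
        raise ValidationError("align_with_trace expects a 1 Hz sequence")
    n = min(len(seq_1hz), len(trace))
    if n == 0:
        raise ValidationError("empty inputs")
    frame_times = seq_1hz.times[:n]
    idx = np.searchsorted(trace.times, frame_times)
    idx = np.clip(idx, 1, len(trace) - 1)
    left = trace.times[idx - 1]
    right = trace.times[idx]
    nearest = np.where(frame_times - left <= right - frame_times, idx - 1, idx)
    mismatch = np.abs(trace.times[nearest] - frame_times)
    if mismatch.max() > tolerance:
        raise ValidationError(
            f"timestamp mismatch {mismatch.max():.3f} s exceeds {tolerance} s"
        )
    return [
        (seq_1hz.frames[i], float(trace.temps[nearest[i]])) for i in range(n)
    ]


def preprocess_sequence(
    seq: UltrasoundFrameSequence,
    trace: TemperatureTrace,
    roi: RoiSpec,
    kernel: int = 3,
) -> tuple[np.ndarray, TemperatureTrace]:
    """Full chain: fuse to 1 Hz, mean-filter, cut ROI, align with the trace.

    Returns (patches, aligned_trace) with ``patches`` a (T, size, size) float
    array, one patch per trace sample.
    """
    fused = temporal_fuse(seq, target_rate=1.0)
    pairs = align_with_trace(fused, trace)
    patches = np.stack(
        [extract_roi(mean_filter(frame, kernel), roi) for frame, _ in pairs]
    )
    temps = np.array([t for _, t in pairs])
    times = fused.times[: len(pairs)]
    return patches, TemperatureTrace(times, temps)
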