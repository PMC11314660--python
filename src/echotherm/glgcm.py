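"""Gray-level gradient co-occurrence matrix (GLGCM) texture features.

The GLGCM is the joint histogram of quantised pixel gray level and quantised
gradient magnitude at the same pixel: combining brightness (echo intensity)
with edge structure captures how ultrasound texture drifts with temperature.
From the normalised matrix H the second-order descriptors of the classical
gray-gradient set are computed; the five used for temperature modelling are
average gray level, gray-level entropy, mixture entropy, inertia and inverse
difference moment, complemented at series level by the gray-temperature
gradient (ratio of temperature change to gray-level change over a 5 s lag).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datatypes import FeatureSeries, TemperatureTrace, ValidationError

__all__ = [
    "QuantizedImagePair",
    "GLGCMatrix",
    "FeatureRanking",
    "gradient_image",
    "quantize_pair",
    "build_glgcm",
    "compute_features",
    "gray_temperature_grad",
    "extract_feature_series",
    "pearson_rank",
    "CORE_FEATURES",
]

#: matrix-level descriptors used as default model channels (Table-set order)
CORE_FEATURES = (
    "average_gray_level",
    "gray_level_entropy",
    "mixture_entropy",
    "inertia",
    "inverse_difference_moment",
)


@dataclass
class QuantizedImagePair:
    """Gray and gradient images quantised to {0..N-1} x {0..M-1}."""

    F: np.ndarray
    G: np.ndarray
    N: int
    M: int
    f_min: float
    f_max: float
    g_max: float


@dataclass
class GLGCMatrix:
    """Joint gray/gradient count matrix ``h`` and its normalisation ``H``."""

    h: np.ndarray
    H: np.ndarray
    N: int
    M: int


@dataclass
class FeatureRanking:
    """Features sorted by |Pearson r| with temperature, descending."""

    entries: list[tuple[str, float]]
    degenerate: list[str]  # zero-variance channels reported with r = 0


def gradient_image(frame: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude with replicate-padded borders."""
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or min(frame.shape) < 3:
        raise ValidationError("frame must be 2D and at least 3x3")
    gx = ndimage.sobel(frame, axis=1, mode="nearest")
    gy = ndimage.sobel(frame, axis=0, mode="nearest")
    return np.hypot(gx, gy)


def quantize_pair(
    f: np.ndarray,
    g: np.ndarray,
    N: int = 16,
    M: int = 16,
    f_range: tuple[float, float] | None = None,
    g_max: float | None = None,
) -> QuantizedImagePair:
    """Min-max quantise gray to N levels and gradient to M levels.

    ``F = floor((f - f_min) / (f_max - f_min) * N)`` clipped to N-1 (a constant
    image maps to level 0); ``G = floor(g / g_max * M)`` clipped to M-1.  By
    default the extrema of the images themselves are used; for sequence-level
    feature extraction pass a fixed ``f_range`` (e.g. the 8-bit range) so the
    gray scale is comparable across frames.
    """
    f = np.asarray(f, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if f.shape != g.shape:
        raise ValidationError("gray and gradient images must share a shape")
    if N < 2 or M < 2:
        raise ValidationError("N and M must be >= 2")
    f_min, f_max = f_range if f_range is not None else (f.min(), f.max())
    if f_max > f_min:
        F = np.floor((f - f_min) / (f_max - f_min) * N)
        F = np.clip(F, 0, N - 1).astype(np.int64)
    else:
        F = np.zeros(f.shape, dtype=np.int64)
    gm = float(g_max) if g_max is not None else float(g.max())
    if gm > 0:
        G = np.floor(g / gm * M)
        G = np.clip(G, 0, M - 1).astype(np.int64)
    else:
        G = np.zeros(g.shape, dtype=np.int64)
    return QuantizedImagePair(F, G, N, M, float(f_min), float(f_max), gm)


def build_glgcm(q: QuantizedImagePair) -> GLGCMatrix:
    """Count co-occurrences h[x, y] = #{pixels with F = x and G = y}."""
    flat = q.F.ravel() * q.M + q.G.ravel()
    h = np.bincount(flat, minlength=q.N * q.M).reshape(q.N, q.M)
    H = h / h.sum()
    return GLGCMatrix(h=h, H=H, N=q.N, M=q.M)


def _entropy(p: np.ndarray) -> float:
    """Natural-log entropy with the 0*log(0) := 0 convention."""
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def compute_features(glg: GLGCMatrix, all_descriptors: bool = False) -> dict[str, float]:
    """Second-order texture descriptors from the normalised GLGCM.

    Returns the five core descriptors by default; ``all_descriptors=True``
    adds the remainder of the classical gray-gradient set (marginal dominance,
    non-uniformity, energy, means, standard deviations, correlation, gradient
    entropy), all computed from H so they are invariant to the total count.
    """
    H = glg.H
    if abs(H.sum() - 1.0) > 1e-9:
        raise ValidationError("H is not normalized")
    N, M = H.shape
    x = np.arange(N, dtype=float)[:, None]
    y = np.arange(M, dtype=float)[None, :]
    Hx = H.sum(axis=1)  # gray marginal
    Hy = H.sum(axis=0)  # gradient marginal
    diff2 = (x - y) ** 2

    feats = {
        "average_gray_level": float((np.arange(N) * Hx).sum()),
        "gray_level_entropy": _entropy(Hx),
        "mixture_entropy": _entropy(H.ravel()),
        "inertia": float((diff2 * H).sum()),
        "inverse_difference_moment": float((H / (1.0 + diff2)).sum()),
    }
    if all_descriptors:
        mu_x = feats["average_gray_level"]
        mu_y = float((np.arange(M) * Hy).sum())
        sd_x = float(np.sqrt(((np.arange(N) - mu_x) ** 2 * Hx).sum()))
        sd_y = float(np.sqrt(((np.arange(M) - mu_y) ** 2 * Hy).sum()))
        corr = float(((x - mu_x) * (y - mu_y) * H).sum())
        corr = corr / (sd_x * sd_y) if sd_x > 0 and sd_y > 0 else 0.0
        feats.update(
            {
                "small_gradient_dominance": float(
                    (Hy / (np.arange(M) + 1.0) ** 2).sum()
                ),
                "large_gradient_dominance": float((np.arange(M) ** 2 * Hy).sum()),
                "gray_nonuniformity": float((Hx**2).sum()),
                "gradient_nonuniformity": float((Hy**2).sum()),
                "energy": float((H**2).sum()),
                "gradient_mean": mu_y,
                "gray_std": sd_x,
                "gradient_std": sd_y,
                "correlation": corr,
                "gradient_entropy": _entropy(Hy),
            }
        )
    return feats


def gray_temperature_grad(
    avgl: np.ndarray,
    temps: np.ndarray,
    lag: int = 5,
    eps: float = 1e-9,
) -> np.ndarray:
    """Ratio of temperature change to gray-level change over ``lag`` samples.

    ``out[t] = (T[t+lag] - T[t]) / (AVGL[t+lag] - AVGL[t])``.  Where the
    denominator is smaller than ``eps`` the previous value is carried forward
    (0 at the series start); the final ``lag`` positions carry the last value
    so the output length matches the input.
    """
    avgl = np.asarray(avgl, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if avgl.shape != temps.shape or avgl.ndim != 1:
        raise ValidationError("avgl and temps must be equal-length 1D arrays")
    if lag < 1:
        raise ValidationError("lag must be >= 1")
    n = len(avgl)
    if n <= lag:
        raise ValidationError("series must be longer than lag")
    out = np.empty(n)
    prev = 0.0
    for t in range(n - lag):
        da = avgl[t + lag] - avgl[t]
        if abs(da) < eps:
            out[t] = prev
        else:
            out[t] = (temps[t + lag] - temps[t]) / da
            prev = out[t]
    out[n - lag:] = out[n - lag - 1]
    return out


def extract_feature_series(
    patches: np.ndarray,
    trace: TemperatureTrace,
    N: int = 16,
    M: int = 16,
    lag: int = 5,
    gray_range: tuple[float, float] | None = (0.0, 255.0),
    all_descriptors: bool = False,
) -> FeatureSeries:
    """Per-patch GLGCM descriptors plus the gray-temperature gradient.

    One patch per trace sample.  Gray levels are quantised against the fixed
    ``gray_range`` (pass None for per-patch extrema) and gradients against the
    sequence-wide maximum, so feature values are comparable along the series.
    The gray-temperature gradient channel uses the raw patch mean gray level
    and the measured temperatures; it embeds the prediction target and is
    excluded from the default model channels.
    """
    patches = np.asarray(patches)
    if len(patches) != len(trace):
        raise ValidationError(
            f"{len(patches)} patches vs {len(trace)} trace samples"
        )
    grads = [gradient_image(p) for p in patches]
    g_max = max(float(g.max()) for g in grads)
    rows: list[dict[str, float]] = []
    for patch, grad in zip(patches, grads):
        q = quantize_pair(patch, grad, N, M, f_range=gray_range, g_max=g_max)
        rows.append(compute_features(build_glgcm(q), all_descriptors))
    channels = {
        name: np.array([r[name] for r in rows]) for name in rows[0]
    }
    raw_mean = patches.reshape(len(patches), -1).mean(axis=1)
    channels["gray_temperature_grad"] = gray_temperature_grad(
        raw_mean, trace.temps, lag=lag
    )
    # canonical channel order: the six modelling features first
    order = list(CORE_FEATURES[:2]) + ["gray_temperature_grad"] + list(
        CORE_FEATURES[2:]
    )
    ordered = {name: channels.pop(name) for name in order}
    ordered.update(channels)
    return FeatureSeries(trace.times.copy(), ordered, temps=trace.temps.copy())


def pearson_rank(fs: FeatureSeries, trace: TemperatureTrace) -> FeatureRanking:
    """Rank feature channels by |Pearson correlation| with temperature."""
    if len(fs) != len(trace):
        raise ValidationError("feature series and trace length mismatch")
    if len(fs) < 3:
        raise ValidationError("need at least 3 samples")
    t = trace.temps - trace.temps.mean()
    st = np.sqrt((t**2).mean())
    entries = []
    degenerate = []
    for name, series in fs.channels.items():
        xc = series - series.mean()
        sx = np.sqrt((xc**2).mean())
        if sx == 0 or st == 0:
            warnings.warn(
                f"channel {name!r} has zero variance; reporting r = 0",
                RuntimeWarning,
                stacklevel=2,
            )
            degenerate.append(name)
            entries.append((name, 0.0))
            continue
        r = float((xc * t).mean() / (sx * st))
        entries.append((name, r))
    entries.sort(key=lambda e: abs(e[1]), reverse=True)
    return FeatureRanking(entries=entries, degenerate=degenerate)
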