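"""FFT-based multi-period decomposition of feature time series.

A length-T multichannel series is decomposed by (1) computing each channel's
DFT amplitude spectrum over frequency indices 1..floor(T/2), (2) normalising
each channel's spectrum by its own maximum so channels with different units
contribute equally, (3) averaging across channels and picking the top-k
frequency indices.  Each selected frequency f corresponds to a period
p = ceil(T/f), and the series can be zero-padded and folded into a (p, f)
tensor whose columns are successive cycles — the representation the
regression network's 2D attention blocks operate on.

Heating series are dominated by the saturating temperature trend, whose
spectral leakage would otherwise occupy the lowest frequency bins, so the
spectrum is computed on linearly detrended data by default (the scipy
periodogram convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .datatypes import ValidationError

__all__ = [
    "PeriodDecomposition",
    "Tensor2D",
    "fft_period_select",
    "reshape_2d",
    "inverse_reshape",
]


@dataclass
class PeriodDecomposition:
    """Top-k spectral components of a series: frequency indices, periods
    (samples per cycle) and channel-averaged normalised amplitudes."""

    frequencies: list[int]
    periods: list[int]
    amplitudes: np.ndarray
    series_length: int


@dataclass
class Tensor2D:
    """A series folded period-wise: rows = position within a period,
    columns = successive cycles; ``pad_length`` zeros were appended."""

    values: np.ndarray
    pad_length: int


def fft_period_select(
    x: np.ndarray,
    k: int,
    detrend: str | None = "linear",
) -> PeriodDecomposition:
    """Select the k dominant periods of a (T,) or (T, C) series.

    Ties in averaged amplitude break toward the lower frequency.  Raises if
    the detrended series is constant (no periodicity to select).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValidationError("series must be 1D or 2D (T, channels)")
    T = x.shape[0]
    if T < 4:
        raise ValidationError("series too short (need T >= 4)")
    if k < 1 or k > T // 2:
        raise ValidationError(f"k must lie in [1, {T // 2}]")
    scale = np.abs(x).max(axis=0)
    if detrend is not None:
        x = signal.detrend(x, axis=0, type=detrend)
    spectrum = np.abs(np.fft.rfft(x, axis=0))[1 : T // 2 + 1]  # indices 1..T//2
    peak = spectrum.max(axis=0)
    # a constant (or, after detrending, purely linear) channel leaves only
    # float rounding noise in its spectrum; treat it as silent
    nonzero = peak > 1e-9 * np.maximum(scale, 1.0)
    if not nonzero.any():
        raise ValidationError("no periodicity: all channel spectra are zero")
    normalized = np.zeros_like(spectrum)
    normalized[:, nonzero] = spectrum[:, nonzero] / peak[nonzero]
    avg = normalized.mean(axis=1)
    order = np.argsort(-avg, kind="stable")  # stable: ties -> lower frequency
    freqs = [int(i) + 1 for i in order[:k]]
    periods = [int(np.ceil(T / f)) for f in freqs]
    return PeriodDecomposition(
        frequencies=freqs,
        periods=periods,
        amplitudes=avg[order[:k]].copy(),
        series_length=T,
    )


def reshape_2d(x: np.ndarray, f: int, p: int) -> Tensor2D:
    """Fold a length-T series into a (p, f) tensor, zero-padding to p*f.

    Element t of the (padded) series lands at row ``t % p``, column ``t // p``:
    column j holds the j-th cycle of length p.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError("reshape_2d expects a 1D series")
    T = len(x)
    if f < 1 or p < 1 or p * f < T:
        raise ValidationError(f"p*f = {p * f} cannot hold {T} samples")
    pad = p * f - T
    padded = np.concatenate([x, np.zeros(pad)]) if pad else x
    return Tensor2D(values=padded.reshape(f, p).T.copy(), pad_length=pad)


def inverse_reshape(t: Tensor2D, T: int) -> np.ndarray:
    """Unfold a period tensor back to the original length-T series."""
    flat = t.values.T.ravel()
    if T > flat.size:
        raise ValidationError(f"T = {T} exceeds tensor capacity {flat.size}")
    return flat[:T].copy()
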