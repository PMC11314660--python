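"""Temporal-informed regression network for ultrasound thermometry.

Architecture: the multichannel feature window is linearly embedded and given
a sinusoidal positional encoding, then passes through a stack of period
blocks.  Each block selects the k dominant periods of its input spectrum,
folds the sequence into one (period x cycles) tensor per period, runs a
dual-branch attention module over each tensor, unfolds, and aggregates the k
branch outputs with softmax weights over their spectral amplitudes before a
residual connection and layer normalisation.  A linear head maps each time
step's embedding to a temperature.

The dual-branch module ("Cloblock") splits the embedding channels:
  * a local branch (AttnConv) mixes tokens with a depthwise convolution whose
    output is gated by learned per-position attention weights derived from a
    query-key product, capturing high-frequency local structure;
  * a global branch applies softmax scaled dot-product attention from every
    flattened 2D position onto keys/values pooled over the period axis,
    capturing low-frequency global structure at low cost.
Branch outputs are concatenated on channels and linearly fused.  The design
keeps the trainable-parameter storage well under 0.1 MB so the model suits
portable ultrasound hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .datatypes import ValidationError
from .nn import (
    DepthwiseConv2d,
    Dropout,
    LSTM,
    LayerNorm,
    Linear,
    Module,
    Tensor,
    concatenate,
    no_grad,
    softmax,
)

__all__ = [
    "ModelConfig",
    "Cloblock",
    "TimesBlock",
    "TemperatureNet",
    "LSTMRegressor",
    "count_parameters",
    "select_periods_batch",
]


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the temperature network.

    ``branch_split`` is the fraction of embedding channels given to the local
    branch; the remainder (global branch) must be divisible by ``n_heads``.
    ``window_length`` of at least twice the longest expected period is
    recommended (not enforced).
    """

    n_channels: int = 5
    k_periods: int = 5
    embed_dim: int = 16
    n_blocks: int = 2
    n_heads: int = 2
    local_kernel: int = 3
    branch_split: float = 0.5
    window_length: int = 96
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.k_periods < 1:
            raise ValidationError("k_periods must be >= 1")
        if self.n_channels < 1 or self.embed_dim < 2 or self.n_blocks < 1:
            raise ValidationError("invalid architecture sizes")
        local = int(self.embed_dim * self.branch_split)
        global_ = self.embed_dim - local
        if local < 1 or global_ < 1:
            raise ValidationError("branch split leaves an empty branch")
        if global_ % self.n_heads != 0:
            raise ValidationError(
                f"global branch width {global_} not divisible by "
                f"{self.n_heads} heads"
            )

    @property
    def local_dim(self) -> int:
        return int(self.embed_dim * self.branch_split)

    @property
    def global_dim(self) -> int:
        return self.embed_dim - self.local_dim

    def to_dict(self) -> dict:
        return asdict(self)


def select_periods_batch(
    x: np.ndarray, k: int, detrend: bool = True
) -> tuple[list[int], list[int], np.ndarray]:
    """Batch variant of period selection used inside the network.

    ``x`` is (batch, T, channels); spectra are max-normalised per (sample,
    channel) and averaged over both, so every window and embedding channel
    votes equally.  Degenerate (constant) batches fall back to the k lowest
    frequencies with uniform amplitudes rather than failing mid-training.
    """
    b, T, c = x.shape
    if detrend:
        t = np.arange(T)
        t = (t - t.mean()) / np.sqrt(((t - t.mean()) ** 2).mean())
        slope = np.einsum("btc,t->bc", x, t) / T
        x = x - slope[:, None, :] * t[None, :, None]
        x = x - x.mean(axis=1, keepdims=True)
    spectrum = np.abs(np.fft.rfft(x, axis=1))[:, 1 : T // 2 + 1]
    peak = spectrum.max(axis=1, keepdims=True)
    np.divide(spectrum, peak, out=spectrum, where=peak > 0)
    avg = spectrum.mean(axis=(0, 2))
    kk = min(k, T // 2)
    if not np.any(avg > 0):
        freqs = list(range(1, kk + 1))
        return freqs, [int(np.ceil(T / f)) for f in freqs], np.ones(kk)
    order = np.argsort(-avg, kind="stable")[:kk]
    freqs = [int(i) + 1 for i in order]
    return freqs, [int(np.ceil(T / f)) for f in freqs], avg[order].copy()


class Cloblock(Module):
    """Dual-branch (local AttnConv + global attention) token mixer on
    (batch, p, f, channels) tensors; shape preserving."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        dl, dg = cfg.local_dim, cfg.global_dim
        self.dl, self.dg, self.heads = dl, dg, cfg.n_heads
        # local branch
        self.lq = Linear(dl, dl, rng)
        self.lk = Linear(dl, dl, rng)
        self.lv = Linear(dl, dl, rng)
        self.conv_gate = DepthwiseConv2d(dl, cfg.local_kernel, rng)
        self.conv_value = DepthwiseConv2d(dl, cfg.local_kernel, rng)
        # global branch
        self.gq = Linear(dg, dg, rng)
        self.gk = Linear(dg, dg, rng)
        self.gv = Linear(dg, dg, rng)
        self.gout = Linear(dg, dg, rng)
        self.fuse = Linear(cfg.embed_dim, cfg.embed_dim, rng)
        self.drop = Dropout(cfg.dropout)

    def __call__(self, x: Tensor, return_attention: bool = False):
        b, p, f, _ = x.shape
        xl = x[..., : self.dl]
        xg = x[..., self.dl :]

        # local: depthwise-conv token mixing gated by per-position attention
        gate = (self.conv_gate(self.lq(xl) * self.lk(xl))).tanh()
        local = gate * self.conv_value(self.lv(xl))

        # global: softmax attention from every flattened 2D position onto
        # keys/values pooled over the period axis (one summary per cycle),
        # the standard pooled-attention economy for long token grids
        L = p * f
        flat = xg.reshape(b, L, self.dg)
        pooled = xg.mean(axis=1)  # (b, f, dg): cycle summaries
        dh = self.dg // self.heads

        def heads(t, n):  # (b, n, dg) -> (b, h, n, dh)
            return t.reshape(b, n, self.heads, dh).transpose(0, 2, 1, 3)

        q = heads(self.gq(flat), L)
        k = heads(self.gk(pooled), f)
        v = heads(self.gv(pooled), f)
        attn = softmax(q @ k.swapaxes(-1, -2) * (1.0 / np.sqrt(dh)), axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b, L, self.dg)
        global_ = self.gout(ctx).reshape(b, p, f, self.dg)

        out = self.drop(self.fuse(concatenate([local, global_], axis=-1)))
        if return_attention:
            return out, attn
        return out


class TimesBlock(Module):
    """Multi-period 2D folding block with amplitude-weighted aggregation."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.mixer = Cloblock(cfg, rng)
        self.norm = LayerNorm(cfg.embed_dim)

    def __call__(self, x: Tensor) -> Tensor:
        b, T, d = x.shape
        freqs, periods, amps = select_periods_batch(x.data, self.cfg.k_periods)
        branches = []
        for f, p in zip(freqs, periods):
            pad = p * f - T
            folded = (
                x.pad_axis(1, 0, pad)
                .reshape(b, f, p, d)
                .transpose(0, 2, 1, 3)  # (b, p, f, d): rows = phase, cols = cycle
            )
            mixed = self.mixer(folded)
            unfolded = mixed.transpose(0, 2, 1, 3).reshape(b, p * f, d)[:, :T, :]
            branches.append(unfolded)
        w = np.exp(amps - amps.max())
        w = w / w.sum()
        agg = branches[0] * w[0]
        for wi, branch in zip(w[1:], branches[1:]):
            agg = agg + branch * wi
        return self.norm(x + agg)


def _positional_encoding(T: int, d: int) -> np.ndarray:
    pos = np.arange(T)[:, None]
    i = np.arange(d)[None, :]
    angles = pos / np.power(10000.0, (2 * (i // 2)) / d)
    pe = np.where(i % 2 == 0, np.sin(angles), np.cos(angles))
    return pe


class TemperatureNet(Module):
    """Sequence-to-sequence temperature regressor over feature windows."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.embed = Linear(cfg.n_channels, cfg.embed_dim, rng)
        self.drop = Dropout(cfg.dropout)
        self.blocks = [TimesBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        # zero-init head: at initialisation the model is exactly its linear
        # bypass, and the period blocks learn the residual structure
        self.head = Linear(cfg.embed_dim, 1, rng, zero_init=True)
        # direct per-step linear bypass: the period blocks then only need to
        # model the residual (the periodic structure), not the level map
        self.skip = Linear(cfg.n_channels, 1, rng)
        self.pe = _positional_encoding(cfg.window_length, cfg.embed_dim)

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3 or x.shape[2] != self.cfg.n_channels:
            raise ValidationError(
                f"expected (batch, T, {self.cfg.n_channels}) input, got {x.shape}"
            )
        if x.shape[1] != self.cfg.window_length:
            raise ValidationError(
                f"window length {x.shape[1]} != configured "
                f"{self.cfg.window_length}"
            )
        h = self.drop(self.embed(x) + Tensor(self.pe))
        for block in self.blocks:
            h = block(h)
        b, T, _ = x.shape
        return (self.head(h) + self.skip(x)).reshape(b, T)

    def set_rng(self, rng: np.random.Generator) -> None:
        """Give every dropout layer the training RNG."""
        for m in self.modules():
            if isinstance(m, Dropout):
                m.rng = rng

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Deterministic forward pass (eval mode, no graph)."""
        self.set_training(False)
        with no_grad():
            out = self(Tensor(windows)).data
        return out


class LSTMRegressor(Module):
    """Single-layer recurrent baseline with per-step linear readout."""

    def __init__(self, n_channels: int, hidden: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hidden_size = hidden
        self.lstm = LSTM(n_channels, hidden, rng)
        self.head = Linear(hidden, 1, rng)
        self.n_channels = n_channels

    def __call__(self, x: Tensor) -> Tensor:
        b, T, _ = x.shape
        return self.head(self.lstm(x)).reshape(b, T)

    def set_rng(self, rng: np.random.Generator) -> None:
        pass

    def predict(self, windows: np.ndarray) -> np.ndarray:
        self.set_training(False)
        with no_grad():
            out = self(Tensor(windows)).data
        return out


def count_parameters(cfg: ModelConfig) -> tuple[int, int]:
    """Exact trainable-scalar count of the configured network and its
    float32 storage footprint in bytes."""
    net = TemperatureNet(cfg)
    n = net.n_parameters()
    return n, 4 * n


def lstm_hidden_for_budget(n_channels: int, min_params: int) -> int:
    """Smallest LSTM hidden size whose parameter count reaches ``min_params``
    (keeps the baseline's capacity at least that of the primary model)."""
    h = 1
    while True:
        params = 4 * (h * (n_channels + h) + h) + h + 1
        if params >= min_params:
            return h
        h += 1
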