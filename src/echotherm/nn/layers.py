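"""Network building blocks on top of the autodiff engine.

Conventions follow the common deep-learning layer zoo: Glorot-uniform
initialisation for dense weights, channels-last layout everywhere
(batch, ..., channels), and an Adam optimiser with optional decoupled-style
L2 weight decay added to the gradient.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Dropout",
    "DepthwiseConv2d",
    "LSTM",
    "Adam",
]


class Module:
    """Base class: children registered as attributes, parameters collected."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in vars(self).values():
            mods.extend(_collect_modules(value))
        return mods

    def set_training(self, flag: bool) -> None:
        for m in self.modules():
            m.training = flag

    training: bool = True

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.astype(np.float64).copy()


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_modules(value) -> list[Module]:
    if isinstance(value, Module):
        return value.modules()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_modules(v))
        return out
    return []


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        xhat = xc / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        self.p = float(p)
        self.rng: np.random.Generator | None = None

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0 or self.rng is None:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution on (batch, H, W, C), zero padding.

    Forward and backward are fused into one graph node (the shifted-slice
    sums run in plain numpy), which matters because these convolutions sit
    inside the innermost period branches.
    """

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.kernel = kernel
        limit = np.sqrt(6.0 / (kernel * kernel))
        self.weight = Tensor(
            rng.uniform(-limit, limit, size=(kernel, kernel, channels)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        k = self.kernel
        r = k // 2
        b, h, w, c = x.shape
        weight, bias = self.weight, self.bias
        xp = np.pad(x.data, ((0, 0), (r, r), (r, r), (0, 0)))
        out_data = np.broadcast_to(bias.data, (b, h, w, c)).copy()
        for di in range(k):
            for dj in range(k):
                out_data += xp[:, di:di + h, dj:dj + w, :] * weight.data[di, dj]

        def backward(g):
            if bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 1, 2)))
            if weight.requires_grad:
                gw = np.empty_like(weight.data)
                for di in range(k):
                    for dj in range(k):
                        gw[di, dj] = np.einsum(
                            "bhwc,bhwc->c", g, xp[:, di:di + h, dj:dj + w, :]
                        )
                weight._accumulate(gw)
            if x.requires_grad:
                gp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gp[:, di:di + h, dj:dj + w, :] += g * weight.data[di, dj]
                x._accumulate(gp[:, r:r + h, r:r + w, :])

        return Tensor._make(out_data, (x, weight, bias), backward)


class LSTM(Module):
    """Single-layer LSTM over (batch, T, C); returns per-step hidden states."""

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        self.wx = Linear(n_in, 4 * hidden, rng)
        self.wh = Linear(hidden, 4 * hidden, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        b, t, _ = x.shape
        h = Tensor(np.zeros((b, self.hidden)))
        c = Tensor(np.zeros((b, self.hidden)))
        hs = []
        nh = self.hidden
        for step in range(t):
            gates = self.wx(x[:, step, :]) + self.wh(h)
            i = gates[:, 0 * nh:1 * nh].sigmoid()
            f = gates[:, 1 * nh:2 * nh].sigmoid()
            g = gates[:, 2 * nh:3 * nh].tanh()
            o = gates[:, 3 * nh:4 * nh].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            hs.append(h.reshape(b, 1, nh))
        return concatenate(hs, axis=1)


class Adam:
    """Adam optimiser; weight_decay adds classic L2 to the gradient."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
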