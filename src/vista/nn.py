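"""Neural-network building blocks (modules, layers, AdamW) on the autodiff core.

Layout conventions follow the common deep-learning ones: images are NCDHW,
feature sequences are (T, D).  All parameters are float32 by default; float64
is available for gradient-checking at test time.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, conv3d, dropout


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    training: bool = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in self.named_parameters():
            v.data = state[k].copy()
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm3d):
                m.running_mean = state[f"__bn{i}.running_mean"].copy()
                m.running_var = state[f"__bn{i}.running_var"].copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, (in_features, out_features)).astype(dtype),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int, padding: int, rng: np.random.Generator,
                 dtype=np.float32):
        fan_in = in_channels * kernel_size ** 3
        scale = np.sqrt(2.0 / fan_in)
        shape = (out_channels, in_channels) + (kernel_size,) * 3
        self.weight = Tensor(rng.normal(0.0, scale, shape).astype(dtype),
                             requires_grad=True)
        self.bias = Tensor(np.zeros((1, out_channels, 1, 1, 1), dtype=dtype),
                           requires_grad=True)
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.stride, self.padding) + self.bias


class BatchNorm3d(Module):
    """Per-channel batch normalization over (N, D, H, W); running stats in eval."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=dtype),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=dtype),
                           requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1, 1), dtype=dtype)
        self.running_var = np.ones((1, channels, 1, 1, 1), dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            xhat = (x - Tensor(self.running_mean)) * (
                Tensor((self.running_var + self.eps) ** -0.5))
        return xhat * self.gamma + self.beta


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x: Tensor) -> Tensor:
        if self.rng is None:
            return x
        return dropout(x, self.p, self.rng, self.training)


def seed_dropout(module: Module, rng: np.random.Generator | None):
    """Attach one generator to every Dropout in `module` (None disables)."""
    for m in module.modules():
        if isinstance(m, Dropout):
            m.rng = rng


class LSTMCell(Module):
    """Standard LSTM cell with forget/input/output gating (gate order i,f,g,o)."""

    def __init__(self, input_dim: int, hidden_dim: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.wx = Linear(input_dim, 4 * hidden_dim, rng, dtype)
        self.wh = Linear(hidden_dim, 4 * hidden_dim, rng, dtype)
        self.hidden_dim = hidden_dim
        # forget-gate bias at 1: remember by default
        b = self.wx.bias.data
        b[hidden_dim:2 * hidden_dim] = 1.0

    def forward(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        hd = self.hidden_dim
        gates = self.wx(x) + self.wh(h)
        i = gates[..., :hd].sigmoid()
        f = gates[..., hd:2 * hd].sigmoid()
        g = gates[..., 2 * hd:3 * hd].tanh()
        o = gates[..., 3 * hd:].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class AdamW:
    """AdamW: Adam moments with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data -= self.lr * (update + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
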