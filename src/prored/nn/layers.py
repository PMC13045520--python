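"""Trainable layers built on the autodiff Tensor.

Initialisation draws from a ``numpy.random.Generator`` passed in explicitly,
so a model seed fully determines the weights.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module", "Conv2d", "Linear", "BatchNorm2d", "LayerNorm",
    "MultiHeadSelfAttention", "Mlp", "TransformerBlock",
]


class Module:
    """Minimal module container: parameter discovery, train/eval mode,
    flat state-dict serialization."""

    def __init__(self):
        self.training = True

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _own_params(self):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: buf.copy() for name, buf in self.buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state dict")
            if state[name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name!r}")
            p.data = state[name].astype(np.float32).copy()
        for name, buf in self.buffers():
            key = "buffer:" + name
            if key in state:
                buf[...] = state[key]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init at ±2 std (resampling rejected draws)."""
    x = rng.normal(0.0, std, size=shape)
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(x) > 2 * std
    return x.astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, padding: int = 0,
                 rng: np.random.Generator | None = None, bias: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel * kernel
        std = float(np.sqrt(2.0 / fan_in))  # He init for ReLU stacks
        self.weight = Tensor(rng.normal(0.0, std, (cout, cin, kernel, kernel)), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True) if bias else None
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_trunc_normal(rng, (fin, fout)), requires_grad=True)
        self.bias = Tensor(np.zeros(fout), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(c) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(c) - self.running_var)
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator | None = None):
        super().__init__()
        if dim % heads:
            raise ValueError(f"embed dim {dim} not divisible by {heads} heads")
        self.heads = heads
        self.head_dim = dim // heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def _split(self, t: Tensor, b: int, n: int) -> Tensor:
        # (B, N, D) -> (B, heads, N, head_dim)
        return t.reshape(b, n, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor) -> Tensor:
        b, n, _ = x.shape
        q = self._split(self.q(x), b, n)
        k = self._split(self.k(x), b, n)
        v = self._split(self.v(x), b, n)
        scale = 1.0 / np.sqrt(self.head_dim)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale  # (B, heads, N, N)
        attn = scores.softmax(axis=-1)
        out = attn @ v  # (B, heads, N, head_dim)
        out = out.transpose(0, 2, 1, 3).reshape(b, n, self.heads * self.head_dim)
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class TransformerBlock(Module):
    """Pre-norm residual block: z' = MSA(LN(z)) + z ; z = MLP(LN(z')) + z'."""

    def __init__(self, dim: int, heads: int, mlp_dim: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_dim, rng)

    def forward(self, z: Tensor) -> Tensor:
        z = self.attn(self.norm1(z)) + z
        return self.mlp(self.norm2(z)) + z
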