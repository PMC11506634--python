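"""Neural-network building blocks on top of the autograd core.

Modules hold :class:`Parameter` tensors and expose ``named_parameters`` for
optimizers and checkpointing.  Initialisation draws from an explicit
``numpy.random.Generator`` so every model is reproducible from a seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concat, conv2d, layer_norm


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery via attribute walking."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = state[k].astype(np.float32).copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = math.sqrt(1.0 / d_in)
        self.weight = Parameter(rng.uniform(-scale, scale, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta, self.eps)


def _split_heads(x: Tensor, n_heads: int) -> Tensor:
    B, N, D = x.shape
    return x.reshape(B, N, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    B, H, N, Dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, N, H * Dh)


class MultiHeadAttention(Module):
    """Scaled dot-product attention; self- or cross- depending on `context`."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 context_dim: int | None = None):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by heads {n_heads}")
        cdim = context_dim if context_dim is not None else dim
        self.n_heads = n_heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(cdim, dim, rng)
        self.v = Linear(cdim, dim, rng)
        self.out = Linear(dim, dim, rng)

    def forward(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        ctx = x if context is None else context
        q = _split_heads(self.q(x), self.n_heads)
        k = _split_heads(self.k(ctx), self.n_heads)
        v = _split_heads(self.v(ctx), self.n_heads)
        scale = 1.0 / math.sqrt(q.shape[-1])
        attn = ((q @ k.transpose(0, 1, 3, 2)) * scale).softmax(axis=-1)
        return self.out(_merge_heads(attn @ v))


class TransformerBlock(Module):
    """Pre-norm transformer block: self-attention + GELU MLP, residual."""

    def __init__(self, dim: int, n_heads: int, mlp_dim: int,
                 rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_dim, rng)
        self.fc2 = Linear(mlp_dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        scale = math.sqrt(1.0 / (c_in * kernel * kernel))
        self.weight = Parameter(
            rng.uniform(-scale, scale, (c_out, c_in, kernel, kernel)))
        self.bias = Parameter(np.zeros(c_out))
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ChannelNorm(Module):
    """LayerNorm over the channel axis of an NCHW map."""

    def __init__(self, channels: int):
        self.ln = LayerNorm(channels)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        flat = x.reshape(B, C, H * W).transpose(0, 2, 1)
        return self.ln(flat).transpose(0, 2, 1).reshape(B, C, H, W)


def sinusoidal_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Fixed sine/cosine positional table, (n_positions, dim), float32."""
    pos = np.arange(n_positions)[:, None].astype(np.float64)
    i = np.arange(dim // 2)[None, :].astype(np.float64)
    freq = np.exp(-math.log(10000.0) * 2.0 * i / dim)
    table = np.zeros((n_positions, dim))
    table[:, 0::2] = np.sin(pos * freq)
    table[:, 1::2] = np.cos(pos * freq)
    return table.astype(np.float32)


def timestep_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    """Sinusoidal embedding of (batched) diffusion timesteps."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    i = np.arange(dim // 2).astype(np.float64)
    freq = np.exp(-math.log(10000.0) * 2.0 * i / dim)
    ang = t[:, None] * freq[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)
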