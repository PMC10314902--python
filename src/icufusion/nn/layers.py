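"""Transformer building blocks on top of the autodiff engine.

Pre-norm encoder blocks (LayerNorm -> multi-head self-attention -> residual,
LayerNorm -> GELU MLP -> residual), the arrangement used by vision
transformers.  Parameter initialisation follows the usual truncated-Gaussian
/ fan-in conventions, driven by an injected ``numpy.random.Generator`` so a
model build is fully determined by its seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "EncoderBlock",
    "TransformerEncoder",
    "concat",
]


class Module:
    """Base class with automatic parameter/submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise ValueError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def _param(rng: np.random.Generator, shape, std: float) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = _param(rng, (in_features, out_features), std=in_features**-0.5)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.in_features:
            raise ValueError(
                f"Linear expected last dim {self.in_features}, got {x.shape[-1]}"
            )
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm() * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        b, s, d = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv(x).reshape(b, s, 3, h, hd)
        # (3, b, h, s, hd)
        qkv = qkv.transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.swapaxes(-1, -2)) * (hd**-0.5)
        att = att.softmax(axis=-1)
        out = att @ v  # (b, h, s, hd)
        out = out.transpose(0, 2, 1, 3).reshape(b, s, d)
        return self.proj(out)


class EncoderBlock(Module):
    """Pre-norm transformer encoder block."""

    def __init__(self, dim: int, heads: int, mlp_hidden: int, rng: np.random.Generator):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, mlp_hidden, rng)
        self.fc2 = Linear(mlp_hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x


class TransformerEncoder(Module):
    """A stack of encoder blocks followed by a final LayerNorm."""

    def __init__(self, dim: int, depth: int, heads: int, mlp_hidden: int,
                 rng: np.random.Generator):
        super().__init__()
        self.depth = depth
        for i in range(depth):
            setattr(self, f"block{i}", EncoderBlock(dim, heads, mlp_hidden, rng))
        self.norm = LayerNorm(dim)

    def __call__(self, x: Tensor) -> Tensor:
        for i in range(self.depth):
            x = getattr(self, f"block{i}")(x)
        return self.norm(x)
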