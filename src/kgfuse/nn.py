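"""Neural-network building blocks on top of the autodiff tensor engine.

Layers follow the usual conventions (Glorot-uniform initialisation,
post-layer-norm transformer blocks, decoupled weight decay in AdamW).
Every source of randomness is an explicit ``numpy.random.Generator`` so
seeded runs are bit-reproducible on CPU.
"""

from __future__ import annotations

import numpy as np

from ._tensor import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Embedding",
           "MultiHeadSelfAttention", "TransformerLayer", "AdamW"]


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
           shape: tuple[int, ...] | None = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape or (fan_in, fan_out))


class Module:
    """Base class: recursive parameter collection and flat state dicts."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)

    def named_parameters(self) -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []
        for key, value in vars(self).items():
            for suffix, p in _named(value):
                out.append((f"{key}{suffix}", p))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Tensor] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _named(value, prefix: str = "") -> list[tuple[str, Tensor]]:
    if isinstance(value, Tensor) and value.requires_grad:
        return [(prefix, value)]
    if isinstance(value, Module):
        return [(f"{prefix}.{n}", p) for n, p in value.named_parameters()]
    if isinstance(value, (list, tuple)):
        out = []
        for i, v in enumerate(value):
            out.extend(_named(v, f"{prefix}[{i}]"))
        return out
    return []


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Tensor(glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


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


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator,
                 scale: float = 0.02):
        self.table = Tensor(rng.normal(0.0, scale, (n, dim)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        flat = self.table.gather(np.asarray(ids).ravel())
        return flat.reshape(*np.asarray(ids).shape, self.table.data.shape[1])


class MultiHeadSelfAttention(Module):
    """Scaled dot-product self-attention with an additive key padding mask."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError("hidden dim must be divisible by head count")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        H, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,L,D) -> (B,H,L,dh)
            return t.reshape(B, L, H, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        bias = np.where(pad_mask[:, None, None, :] > 0, 0.0, -1e9)
        att = (scores + Tensor(bias)).softmax(axis=-1)
        ctx = (att @ v).transpose(0, 2, 1, 3).reshape(B, L, D)
        return self.wo(ctx)


class TransformerLayer(Module):
    """Post-LN block: x -> LN(x + MHSA(x)) -> LN(x + FFN(x))."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator, dropout: float = 0.1):
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng)
        self.ln1 = LayerNorm(dim)
        self.ff1 = Linear(dim, ffn_dim, rng)
        self.ff2 = Linear(ffn_dim, dim, rng)
        self.ln2 = LayerNorm(dim)
        self.dropout = dropout

    def __call__(self, x: Tensor, pad_mask: np.ndarray,
                 rng: np.random.Generator | None = None) -> Tensor:
        x = self.ln1(x + self.attn(x, pad_mask).dropout(self.dropout, rng))
        h = self.ff2(self.ff1(x).relu())
        return self.ln2(x + h.dropout(self.dropout, rng))


class AdamW:
    """Adam with decoupled weight decay (bias-corrected)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
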