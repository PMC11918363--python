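"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based tensor engine sized for the CPU-scale models in this
package (a tiny transformer encoder, a graph attention network, linear
heads).  Only the operations those models need are implemented; each op
records a backward closure and `Tensor.backward` replays the tape in
reverse topological order.

All arrays are float64 for bit-reproducible CPU runs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "segment_sum", "segment_softmax",
           "masked_cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))
        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))
        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    # ------------------------------------------------------------ reshaping
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        axes = axes or tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bw
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        val = self.data.max(axis=axis, keepdims=True)
        out = Tensor(val if keepdims else np.squeeze(val, axis),
                     self.requires_grad, (self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == val)
            # split gradient among ties to keep the op permutation-equivariant
            mask = mask / mask.sum(axis=axis, keepdims=True)
            self._accumulate(mask * g)
        out._backward = bw
        return out

    # ---------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - out.data ** 2))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, slope))
        return out

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(self.data > 0, self.data, neg),
                     self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(
            g * np.where(self.data > 0, 1.0, neg + alpha))
        return out

    # ------------------------------------------------------- structured ops
    def gather(self, indices: np.ndarray, axis: int = 0):
        """Select rows (axis 0 only); gradient scatters with accumulation."""
        if axis != 0:
            raise NotImplementedError("gather supports axis=0 only")
        idx = np.asarray(indices)
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)
        out._backward = bw
        return out

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)  # stop-grad shift
        e = (self - m).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def dropout(self, p: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when rng is None (eval mode) or p == 0."""
        if rng is None or p <= 0.0:
            return self
        keep = (rng.random(self.data.shape) >= p) / (1.0 - p)
        return self * Tensor(keep)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)
    out._backward = bw
    return out


def segment_sum(values: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `values` grouped by `segments` (shape (E, ...) -> (S, ...))."""
    seg = np.asarray(segments)
    data = np.zeros((num_segments,) + values.data.shape[1:])
    np.add.at(data, seg, values.data)
    out = Tensor(data, values.requires_grad, (values,))
    out._backward = lambda g: values._accumulate(g[seg])
    return out


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of `scores` within each segment (per-neighborhood attention)."""
    seg = np.asarray(segments)
    m = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(m, seg, scores.data)  # stop-grad max for stability
    z = (scores - Tensor(m[seg])).exp()
    denom = segment_sum(z, seg, num_segments)
    return z / denom.gather(seg)


def masked_cross_entropy(logits: Tensor, labels: np.ndarray,
                         mask: np.ndarray) -> Tensor:
    """Mean token-level cross-entropy over positions where mask is truthy.

    logits: (..., C); labels: integer array matching logits[...,0];
    masked positions contribute nothing to loss or gradient.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=np.float64)
    n_valid = mask.sum()
    if n_valid == 0:
        raise ValueError("cross-entropy mask selects no positions")
    x = logits.data
    m = x.max(axis=-1, keepdims=True)
    lse = m + np.log(np.exp(x - m).sum(axis=-1, keepdims=True))
    logp = x - lse
    safe_labels = np.where(mask > 0, labels, 0).astype(np.intp)
    picked = np.take_along_axis(logp, safe_labels[..., None], axis=-1)[..., 0]
    loss_val = -(picked * mask).sum() / n_valid
    out = Tensor(loss_val, logits.requires_grad, (logits,))

    def bw(g):
        probs = np.exp(logp)
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, safe_labels[..., None], 1.0, axis=-1)
        grad = (probs - onehot) * mask[..., None] / n_valid
        logits._accumulate(g * grad)
    out._backward = bw
    return out
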