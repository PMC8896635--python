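"""Minimal tape-based reverse-mode automatic differentiation over numpy.

Just enough machinery for a small transformer encoder: broadcast-aware
elementwise arithmetic, batched matmul, softmax/log-softmax, layer
normalization, GELU/ReLU/tanh, embedding lookups, slicing, concatenation
and a fused masked cross-entropy.  Gradients are checked against central
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

IGNORE_INDEX = -100


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reverse numpy broadcasting: reduce ``grad`` down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self) -> None:
        """Accumulate gradients of a scalar output into every parent."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _sum_to_shape(np.asarray(grad), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))
        def bw(g):
            self._accumulate(g)
            other._accumulate(g)
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))
        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))
        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / other.data ** 2)
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))
        def bw(g):
            self._accumulate(np.matmul(g, np.swapaxes(other.data, -1, -2)))
            other._accumulate(np.matmul(np.swapaxes(self.data, -1, -2), g))
        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: self._accumulate(
            g * exponent * self.data ** (exponent - 1))
        return out

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(old))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, a, b))
        return out

    def slice(self, index):
        """Static slicing (basic indexing only)."""
        out = Tensor(self.data[index], parents=(self,))
        def bw(g):
            full = np.zeros_like(self.data)
            full[index] = g
            self._accumulate(full)
        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))
        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# nonlinearities and fused ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accumulate(g * (1.0 - y ** 2))
    return out


def gelu(x: Tensor) -> Tensor:
    """tanh-approximation GELU (the BERT activation)."""
    c = np.sqrt(2.0 / np.pi)
    u = c * (x.data + 0.044715 * x.data ** 3)
    t = np.tanh(u)
    y = 0.5 * x.data * (1.0 + t)
    out = Tensor(y, parents=(x,))
    def bw(g):
        du = c * (1.0 + 3 * 0.044715 * x.data ** 2)
        dy = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t ** 2) * du
        x._accumulate(g * dy)
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(x,))
    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accumulate(s * (g - dot))
    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = Tensor(z - lse, parents=(x,))
    def bw(g):
        s = np.exp(z - lse)
        x._accumulate(g - s * g.sum(axis=axis, keepdims=True))
    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalization over the last axis with learned scale and shift."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, parents=(x, gamma, beta))
    def bw(g):
        d = x.data.shape[-1]
        gamma._accumulate((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        beta._accumulate(g.sum(axis=tuple(range(g.ndim - 1))))
        gx = g * gamma.data
        dx = inv * (gx - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True))
        x._accumulate(dx)
    out._backward = bw
    return out


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row gather with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.int64)
    out = Tensor(weight.data[ids], parents=(weight,))
    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, ids.ravel(), g.reshape(-1, weight.data.shape[1]))
        weight._accumulate(full)
    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    def bw(g):
        splits = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, splits):
            t._accumulate(piece)
    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    out = Tensor(x.data * keep, parents=(x,))
    out._backward = lambda g: x._accumulate(g * keep)
    return out


def cross_entropy_logits(logits: Tensor, labels: np.ndarray,
                         ignore_index: int = IGNORE_INDEX) -> Tensor:
    """Mean cross-entropy over positions whose label != ignore_index.

    ``logits`` has shape (..., C); ``labels`` the matching leading shape.
    With no supervised position the loss is exactly 0 (empty-objective
    convention used by the masked-modeling heads).
    """
    labels = np.asarray(labels, dtype=np.int64)
    flat_logits = logits.reshape(-1, logits.shape[-1])
    flat_labels = labels.reshape(-1)
    supervised = flat_labels != ignore_index
    n_sup = int(supervised.sum())
    if n_sup == 0:
        return Tensor(0.0, parents=(logits,))
    z = flat_logits.data - flat_logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    rows = np.nonzero(supervised)[0]
    cols = flat_labels[supervised]
    loss_val = -logp[rows, cols].mean()
    out = Tensor(loss_val, parents=(flat_logits,))
    def bw(g):
        probs = np.exp(logp)
        grad = np.zeros_like(flat_logits.data)
        grad[rows] = probs[rows]
        grad[rows, cols] -= 1.0
        flat_logits._accumulate(grad * (float(g) / n_sup))
    out._backward = bw
    return out
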