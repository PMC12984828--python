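"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a set transformer on CPU: broadcasting arithmetic,
batched matmul, pointwise nonlinearities, axis reductions, reshapes,
concatenation, and fused primitives for the hot paths (masked softmax and
layer normalization). Gradients are dense float64 arrays accumulated
lazily — a node's buffer is created on first contribution, and freshly
allocated contributions are adopted by reference instead of copied.

All gradient rules are exercised against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph -------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def _acc(self, g: np.ndarray, fresh: bool) -> None:
        """Accumulate a gradient contribution.

        ``fresh`` marks ``g`` as a newly allocated array this node may adopt
        by reference; aliased views are copied on first accumulation.
        """
        if self.grad is None:
            self.grad = g if fresh and g.flags.writeable else np.array(g)
        else:
            self.grad += g

    def _acc_unb(self, g: np.ndarray, fresh: bool) -> None:
        u = _unbroadcast(g, self.shape)
        self._acc(u, fresh or u is not g)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # free the graph
        for node in topo:
            node._parents = ()
            node._backward = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._acc_unb(g, False)
            if other.requires_grad:
                other._acc_unb(g, False)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._acc_unb(g * other.data, True)
            if other.requires_grad:
                other._acc_unb(g * self.data, True)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g * exponent * self.data ** (exponent - 1.0), True)

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bw(g):
            if self.requires_grad:
                self._acc_unb(g @ np.swapaxes(other.data, -1, -2), True)
            if other.requires_grad:
                other._acc_unb(np.swapaxes(self.data, -1, -2) @ g, True)

        out._backward = bw
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                scatter = np.zeros_like(self.data)
                np.add.at(scatter, key, g)
                self._acc(scatter, True)

        out._backward = bw
        return out

    # -- pointwise ---------------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g * out.data, True)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g / self.data, True)

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g * (self.data > 0), True)

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g * (1.0 - out.data**2), True)

        out._backward = bw
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._acc(np.broadcast_to(g, self.shape), False)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw(g):
            if self.requires_grad:
                self._acc(g.reshape(self.shape), False)

        out._backward = bw
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inverse = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._acc(g.transpose(inverse), False)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(
        np.concatenate(datas, axis=axis),
        any(t.requires_grad for t in tensors),
        tuple(tensors),
    )
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                slicer = [slice(None)] * g.ndim
                slicer[axis] = slice(start, stop)
                t._acc(g[tuple(slicer)], False)

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Fused primitives and helpers
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1, additive_mask: np.ndarray | None = None) -> Tensor:
    """Numerically stable softmax as a fused primitive; ``additive_mask``
    (e.g. -inf on padded keys) is added to the logits before normalization.
    Masked entries get exactly 0 weight and propagate no gradient."""
    logits = x.data if additive_mask is None else x.data + additive_mask
    shift = logits.max(axis=axis, keepdims=True)
    shift = np.where(np.isfinite(shift), shift, 0.0)
    with np.errstate(invalid="ignore"):
        e = np.exp(logits - shift)
    alpha = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(alpha, x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            # d softmax: alpha * (g - sum(g * alpha))
            inner = (g * alpha).sum(axis=axis, keepdims=True)
            x._acc(alpha * (g - inner), True)

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis (fused primitive)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    centered = x.data - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = centered * inv
    out = Tensor(
        xhat * gamma.data + beta.data,
        x.requires_grad or gamma.requires_grad or beta.requires_grad,
        (x, gamma, beta),
    )

    def bw(g):
        if gamma.requires_grad:
            gamma._acc_unb(g * xhat, True)
        if beta.requires_grad:
            beta._acc_unb(g, False)
        if x.requires_grad:
            gx = g * gamma.data
            x._acc(
                inv
                * (
                    gx
                    - gx.mean(axis=-1, keepdims=True)
                    - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                ),
                True,
            )

    out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, train: bool) -> Tensor:
    if not train or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * Tensor(keep)


class Adam:
    """Adam optimizer over a dict of parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
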