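"""Minimal reverse-mode automatic differentiation over numpy arrays.

The attention regressor in this package is small (a handful of matrix
products per forward pass), so rather than depending on a deep-learning
framework it runs on this self-contained tape-based engine: a :class:`Tensor`
wraps an ``ndarray``, records its parents, and ``backward()`` walks the tape
in reverse topological order accumulating gradients.  Only the operations the
model needs are implemented; each one supports numpy broadcasting, with
gradients reduced back to the operand's shape.

All gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "layer_norm_op",
    "masked_softmax_op",
    "rope_rotate_op",
]


_GRAD_ENABLED = True


class no_grad:
    """Context manager: ops built inside record no tape (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        if _parents and not _GRAD_ENABLED:
            self.requires_grad = False
            self._parents = ()
            self._backward = None
            return
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = backward
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:
                return g * b, a * g
            if b.ndim == 1:
                # (..., n, k) @ (k,) -> (..., n)
                ga = g[..., None] * b
                gb = (a * g[..., None]).reshape(-1, a.shape[-1]).sum(axis=0)
                return _unbroadcast(ga, self.shape), gb
            if a.ndim == 1:
                # (k,) @ (..., k, m) -> (..., m)
                ga = (b * g[..., None, :]).sum(axis=-1)
                if ga.ndim > 1:
                    ga = ga.reshape(-1, a.shape[0]).sum(axis=0)
                gb = a[:, None] * g[..., None, :]
                return ga, _unbroadcast(gb, other.shape)
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))
        out._backward = lambda g: (g * exponent * self.data ** (exponent - 1),)
        return out

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        data = np.exp(self.data)
        out = Tensor(data, _parents=(self,))
        out._backward = lambda g: (g * data,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def tanh(self):
        data = np.tanh(self.data)
        out = Tensor(data, _parents=(self,))
        out._backward = lambda g: (g * (1.0 - data**2),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))
        out._backward = lambda g: (g * (self.data > 0.0),)
        return out

    def sqrt(self):
        return self**0.5

    # -- reductions & shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), _parents=(self,))
        out._backward = lambda g: (np.swapaxes(g, a, b),)
        return out

    def transpose(self, axes):
        out = Tensor(np.transpose(self.data, axes), _parents=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: (np.transpose(g, inv),)
        return out

    def slice0(self, start: int, stop: int):
        """Slice along the leading axis (gradient scattered back)."""
        out = Tensor(self.data[start:stop], _parents=(self,))
        shape = self.shape

        def backward(g):
            full = np.zeros(shape)
            full[start:stop] = g
            return (full,)

        out._backward = backward
        return out

    # -- autodiff ---------------------------------------------------------
    def backward(self, grad=None):
        """Accumulate gradients into the leaf tensors reachable from here.

        The tape is consumed: interior nodes drop their parent links as they
        are processed (breaking the closure reference cycles), so a graph
        can be backpropagated through only once.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            node._backward = None
            node._parents = ()

    def zero_grad(self):
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def layer_norm_op(x: Tensor, gain: Tensor, bias: Tensor, eps: float) -> Tensor:
    """Fused layer normalization over the last axis.

    y = (x - mean) / sqrt(var + eps) * gain + bias, with the standard
    closed-form backward (cheaper than composing it from primitives).
    """
    x, gain, bias = as_tensor(x), as_tensor(gain), as_tensor(bias)
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(xhat * gain.data + bias.data, _parents=(x, gain, bias))

    def backward(g):
        dxhat = g * gain.data
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        lead = tuple(range(g.ndim - gain.data.ndim))
        dgain = (g * xhat).sum(axis=lead) if lead else g * xhat
        dbias = g.sum(axis=lead) if lead else g
        return dx, _unbroadcast(dgain, gain.shape), _unbroadcast(dbias, bias.shape)

    out._backward = backward
    return out


def masked_softmax_op(logits: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Fused max-subtracted softmax over `axis` restricted to mask==1.

    Masked entries are exactly zero in the output and receive no gradient;
    backward uses dz = y * (g - sum(y * g)).
    """
    logits = as_tensor(logits)
    mask = np.broadcast_to(np.asarray(mask, dtype=np.float64), logits.shape)
    shifted = np.where(mask > 0, logits.data, -np.inf)
    shifted = shifted - np.max(shifted, axis=axis, keepdims=True)
    e = np.exp(shifted) * mask
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(logits,))

    def backward(g):
        inner = (y * g).sum(axis=axis, keepdims=True)
        return (y * (g - inner),)

    out._backward = backward
    return out


def rope_rotate_op(x: Tensor, cos: np.ndarray, sin: np.ndarray) -> Tensor:
    """Fused rotation of consecutive dimension pairs (2i, 2i+1).

    cos/sin have shape broadcastable to x[..., 0::2]; the backward applies
    the inverse rotation to the gradient (rotations are orthogonal).
    """
    x = as_tensor(x)
    x1 = x.data[..., 0::2]
    x2 = x.data[..., 1::2]
    out_data = np.empty_like(x.data)
    out_data[..., 0::2] = x1 * cos - x2 * sin
    out_data[..., 1::2] = x1 * sin + x2 * cos
    out = Tensor(out_data, _parents=(x,))

    def backward(g):
        g1 = g[..., 0::2]
        g2 = g[..., 1::2]
        dx = np.empty_like(g)
        dx[..., 0::2] = g1 * cos + g2 * sin
        dx[..., 1::2] = -g1 * sin + g2 * cos
        return (dx,)

    out._backward = backward
    return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors)
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.array_split(g, splits, axis=axis))

    out._backward = backward
    return out
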