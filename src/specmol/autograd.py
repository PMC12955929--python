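"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The model in :mod:`specmol.network` is small (molecular graphs have tens of
atoms, embedding widths are two-digit), so a lightweight dynamically-built
tape over dense ``float64`` arrays is sufficient for desk-scale training.
Only the operations the network and the training objectives actually use are
implemented; every op defines its vector-Jacobian product in closed form.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack", "Adam", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (fast inference)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make `ndarray <op> Tensor` defer to our reflected operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], Iterable[tuple["Tensor", np.ndarray]]]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = _GRAD_ENABLED and any(p.requires_grad
                                                  for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)

            def _bw():
                for p, g in backward(out.grad):
                    if p.requires_grad:
                        if p.grad is None:
                            p.grad = np.zeros_like(p.data)
                        p.grad += _unbroadcast(g, p.data.shape)

            out._backward = _bw
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        return self._make(self.data + other.data, (self, other),
                          lambda g: ((self, g), (other, g)))

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return self._make(self.data - other.data, (self, other),
                          lambda g: ((self, g), (other, -g)))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: ((self, -g),))

    def __mul__(self, other):
        other = as_tensor(other)
        return self._make(self.data * other.data, (self, other),
                          lambda g: ((self, g * other.data), (other, g * self.data)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self._make(
            self.data / other.data, (self, other),
            lambda g: ((self, g / other.data),
                       (other, -g * self.data / other.data ** 2)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        assert isinstance(p, (int, float))
        return self._make(self.data ** p, (self,),
                          lambda g: ((self, g * p * self.data ** (p - 1)),))

    def __matmul__(self, other):
        other = as_tensor(other)
        return self._make(self.data @ other.data, (self, other),
                          lambda g: ((self, g @ other.data.T),
                                     (other, self.data.T @ g)))

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: ((self, g * out_data),))

    def log(self):
        return self._make(np.log(self.data), (self,),
                          lambda g: ((self, g / self.data),))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,),
                          lambda g: ((self, g / (2.0 * out_data)),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,),
                          lambda g: ((self, g * (1.0 - out_data ** 2)),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,),
                          lambda g: ((self, g * out_data * (1.0 - out_data)),))

    def softplus(self):
        # log(1 + e^x), computed stably; derivative is sigmoid(x)
        out_data = np.logaddexp(0.0, self.data)
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: ((self, g * sig),))

    def mish(self):
        """Mish activation: x * tanh(softplus(x))."""
        return self * self.softplus().tanh()

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the range."""
        inside = (self.data >= lo) & (self.data <= hi)
        return self._make(np.clip(self.data, lo, hi), (self,),
                          lambda g: ((self, g * inside),))

    def relu(self):
        mask = self.data > 0
        return self._make(self.data * mask, (self,),
                          lambda g: ((self, g * mask),))

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            return ((self, np.broadcast_to(gg, self.data.shape).copy()),)

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return ((self, out_data * (g - dot)),)

        return self._make(out_data, (self,), bw)

    def reshape(self, *shape):
        old = self.data.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: ((self, g.reshape(old)),))

    @property
    def T(self):
        return self._make(self.data.T.copy(), (self,), lambda g: ((self, g.T),))

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return ((self, full),)

        return self._make(self.data[idx].copy(), (self,), bw)

    # -- composite helpers ----------------------------------------------------
    def layer_norm(self, eps: float = 1e-5):
        """Feature normalization over the last axis (no affine terms)."""
        mu = self.mean(axis=-1, keepdims=True)
        centred = self - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / (var + eps).sqrt()

    # -- backward pass --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs can be deep through GRU steps)
        while stack:
            node = stack.pop()
            if id(node) in seen:
                continue
            unvisited = [p for p in node._parents
                         if id(p) not in seen and p.requires_grad]
            if unvisited:
                stack.append(node)
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # free the tape
        for node in topo:
            if node is not self:
                node._backward = None
                node._parents = ()


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def _bw():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * data.ndim
                    sl[axis] = slice(lo, hi)
                    g = out.grad[tuple(sl)]
                    if t.grad is None:
                        t.grad = np.zeros_like(t.data)
                    t.grad += g

        out._backward = _bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = _GRAD_ENABLED and any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)

        def _bw():
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    g = np.take(out.grad, i, axis=axis)
                    if t.grad is None:
                        t.grad = np.zeros_like(t.data)
                    t.grad += g

        out._backward = _bw
    return out


class Adam:
    """Adam optimizer over a named parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
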