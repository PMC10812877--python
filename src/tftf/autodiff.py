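"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network here is small (embedding dim 8, six transformer blocks in total),
so a compact tape-based engine over dense numpy arrays is sufficient and keeps
the whole stack dependency-free. Gradients of every primitive are verified
against central finite differences in the test suite.
"""

from __future__ import annotations

import ctypes
import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


def _tune_allocator():
    """Keep large blocks on the heap so attention-sized temporaries are
    recycled between steps.

    Training allocates and frees many ~64 MB (batch, heads, L, L) arrays per
    step; with glibc's default mmap threshold each one is returned to the OS
    on free and re-faulted on the next step, which can dominate runtime on
    kernels with slow fault paths. Raising the mmap threshold and disabling
    heap trimming makes the allocator reuse them. Best-effort and glibc-only;
    silently skipped elsewhere.
    """
    try:
        libc = ctypes.CDLL("libc.so.6")
        libc.mallopt(-3, 1 << 30)  # M_MMAP_THRESHOLD
        libc.mallopt(-1, -1)  # M_TRIM_THRESHOLD
    except Exception:
        pass


_tune_allocator()


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


class Tensor:
    """A numpy array with an optional backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)
            if t._parents:  # free non-leaf grads and graph edges as we go
                t.grad = None
                t._parents = ()
                t._backward = None

    def zero_grad(self):
        self.grad = None

    # -- helpers ----------------------------------------------------------
    def _wrap(self, x):
        """Wrap constants, following this tensor's float dtype so python
        scalars never promote a float32 graph to float64."""
        if isinstance(x, Tensor):
            return x
        a = np.asarray(x)
        if a.dtype != self.data.dtype and a.dtype.kind == "f" and self.data.dtype.kind == "f":
            a = a.astype(self.data.dtype)
        return Tensor(a)

    def _make(self, data, parents, backward):
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        if not req:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_sum_to_shape(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def matmul(self, other):
        other = self._wrap(other)
        out_data = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_sum_to_shape(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_sum_to_shape(gb, other.data.shape))

        return self._make(out_data, (self, other), bwd)

    __matmul__ = matmul

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bwd(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bwd)

    def select(self, index: int, axis: int):
        """Take one index along ``axis`` (e.g. the CLS position)."""

        def bwd(g):
            full = np.zeros_like(self.data)
            sl = [slice(None)] * self.data.ndim
            sl[axis] = index
            full[tuple(sl)] = g
            self._accum(full)

        sl = [slice(None)] * self.data.ndim
        sl[axis] = index
        return self._make(self.data[tuple(sl)], (self,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities --------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), bwd)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def bwd(g):
            self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), bwd)


def softmax(x: Tensor, axis: int = -1, keep: np.ndarray | None = None) -> Tensor:
    """Softmax along ``axis``; positions where ``keep`` is False get weight 0.

    ``keep`` (broadcastable boolean) implements attention padding masks
    without materialising a large additive-bias array.
    """
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    if keep is not None:
        e *= keep
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        x._accum(out_data * (g - dot))

    return x._make(out_data, (x,), bwd)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out_data = gamma.data * xhat + beta.data

    def bwd(g):
        if gamma.requires_grad:
            gamma._accum(_sum_to_shape(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_sum_to_shape(g, beta.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=-1, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (dxhat - m1 - xhat * m2))

    return x._make(out_data, (x, gamma, beta), bwd)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    if ids.min() < 0 or ids.max() >= table.data.shape[0]:
        raise ValueError(
            f"token id out of vocabulary range [0, {table.data.shape[0]})"
        )
    out_data = table.data[ids]

    def bwd(g):
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        table._accum(full)

    return table._make(out_data, (table,), bwd)


def cross_entropy(logits: Tensor, class_idx: np.ndarray) -> Tensor:
    """Mean negative log-softmax of the true class (2-class or general).

    ``class_idx`` holds 0-based class indices.
    """
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsum
    loss = -logp[np.arange(n), class_idx].mean()

    def bwd(g):
        p = np.exp(logp)
        p[np.arange(n), class_idx] -= 1.0
        logits._accum((g / n) * p)

    return logits._make(np.asarray(loss, dtype=logits.data.dtype), (logits,), bwd)


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(self, params: dict, lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar function; test utility."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
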