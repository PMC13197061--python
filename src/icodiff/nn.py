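"""Minimal reverse-mode array autodiff core and optimizer.

A small tape-based engine over numpy ``float32`` arrays providing exactly the
operations the spherical denoising network needs: broadcasting arithmetic,
(batched) matmul, vertex gathering/scattering, reductions, activations,
softmax, concatenation/splitting and zero-padding along the vertex axis.

Gradients accumulate on every :class:`Tensor` in the graph; parameters are
plain Tensors collected by :class:`Module`.  ``no_grad()`` disables taping for
inference-time sampling loops.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = ["Tensor", "Module", "Adam", "no_grad", "concat"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Tensor:
    __slots__ = ("data", "grad", "_prev", "_backward")

    def __init__(self, data, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._prev = _prev if _GRAD_ENABLED else ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph plumbing -------------------------------------------------
    def _make(self, data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED:
            out._prev = prev
            out._backward = backward
        return out

    def backward(self) -> None:
        """Reverse-accumulate gradients from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._prev:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        g = g.astype(np.float32, copy=False)
        t.grad = g if t.grad is None else t.grad + g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            Tensor._accum(self, _unbroadcast(g, self.shape))
            Tensor._accum(other, _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            Tensor._accum(self, _unbroadcast(g * other.data, self.shape))
            Tensor._accum(other, _unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            Tensor._accum(self, _unbroadcast(g / other.data, self.shape))
            Tensor._accum(
                other, _unbroadcast(-g * self.data / other.data**2, other.shape)
            )

        return self._make(out_data, (self, other), bw)

    def matmul(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            Tensor._accum(self, _unbroadcast(ga, self.shape))
            Tensor._accum(other, _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), bw)

    __matmul__ = matmul

    def square(self):
        return self * self

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            Tensor._accum(self, g * 0.5 / np.maximum(out_data, 1e-12))

        return self._make(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            Tensor._accum(self, g * out_data)

        return self._make(out_data, (self,), bw)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            Tensor._accum(self, np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        orig = self.shape

        def bw(g):
            Tensor._accum(self, g.reshape(orig))

        return self._make(out_data, (self,), bw)

    def swapaxes(self, a, b):
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            Tensor._accum(self, np.swapaxes(g, a, b))

        return self._make(out_data, (self,), bw)

    def gather_vertices(self, index: np.ndarray):
        """Gather along the vertex axis of a ``(B, V, C)`` tensor.

        ``index`` is ``(V, K)`` (e.g. the 7-tap 1-ring table); the result is
        ``(B, V, K, C)``.  The backward pass scatter-adds into the source via
        a cached inverse-occurrence table (each vertex appears in only a few
        gather rows, so the scatter becomes a gather + masked sum).
        """
        B, V, C = self.shape
        Vq, K = index.shape
        flat = index.ravel()
        out_data = self.data[:, flat, :].reshape(B, Vq, K, C)
        inv, inv_mask = _inverse_gather_table(index, V)

        def bw(g):
            g2 = g.reshape(B, Vq * K, C)
            gx = (g2[:, inv, :] * inv_mask[None, :, :, None]).sum(axis=2)
            Tensor._accum(self, gx.astype(np.float32, copy=False))

        return self._make(out_data, (self,), bw)

    def take_vertex_prefix(self, n: int):
        """Keep the first ``n`` vertices of a ``(B, V, C)`` tensor (pooling)."""
        out_data = self.data[:, :n, :]
        V = self.shape[1]

        def bw(g):
            pad = np.zeros((g.shape[0], V, g.shape[2]), dtype=np.float32)
            pad[:, :n, :] = g
            Tensor._accum(self, pad)

        return self._make(out_data, (self,), bw)

    def pad_vertices(self, n_total: int):
        """Zero-pad the vertex axis of a ``(B, V, C)`` tensor to ``n_total``."""
        B, V, C = self.shape
        out_data = np.zeros((B, n_total, C), dtype=np.float32)
        out_data[:, :V, :] = self.data

        def bw(g):
            Tensor._accum(self, g[:, :V, :])

        return self._make(out_data, (self,), bw)

    def split_last(self, sizes: tuple):
        """Split along the last axis into tensors of the given widths."""
        outs = []
        start = 0
        for s in sizes:
            sl = slice(start, start + s)
            out_data = self.data[..., sl]
            full_shape = self.shape

            def bw(g, sl=sl):
                gx = np.zeros(full_shape, dtype=np.float32)
                gx[..., sl] = g
                Tensor._accum(self, gx)

            outs.append(self._make(out_data, (self,), bw))
            start += s
        return outs

    # -- nonlinearities --------------------------------------------------
    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out_data = self.data * s

        def bw(g):
            Tensor._accum(self, g * (s * (1.0 + self.data * (1.0 - s))))

        return self._make(out_data, (self,), bw)

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            Tensor._accum(self, out_data * (g - dot))

        return self._make(out_data, (self,), bw)


_INV_GATHER_CACHE: dict = {}


def _inverse_gather_table(index: np.ndarray, n_vertices: int):
    """Occurrence positions of each source vertex in a flattened gather index.

    Returns ``(inv, mask)`` with ``inv`` of shape ``(V, M)`` listing the flat
    positions where vertex ``v`` is gathered (padded with 0) and ``mask``
    marking the valid slots.  Cached on the identity of the index array,
    which the network holds for its lifetime.
    """
    key = (id(index), index.shape)
    hit = _INV_GATHER_CACHE.get(key)
    if hit is not None:
        return hit
    flat = index.ravel()
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat, minlength=n_vertices)
    m = int(counts.max())
    inv = np.zeros((n_vertices, m), dtype=np.int64)
    mask = np.zeros((n_vertices, m), dtype=np.float32)
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    for v in range(n_vertices):
        c = counts[v]
        inv[v, :c] = order[starts[v] : starts[v] + c]
        mask[v, :c] = 1.0
    _INV_GATHER_CACHE[key] = (inv, mask)
    return inv, mask


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5) -> Tensor:
    """Fused group normalization over (vertices, channels-within-group).

    Forward and backward are closed-form (single fused op) rather than
    composed from primitives — this sits in the inner loop of every ResBlock.
    """
    B, V, C = x.shape
    g = groups
    cg = C // g
    n = V * cg
    xg = x.data.reshape(B, V, g, cg)
    s1 = np.einsum("bvgc->bg", xg)
    s2 = np.einsum("bvgc,bvgc->bg", xg, xg)
    mu = (s1 / n)[:, None, :, None]
    var = (s2 / n)[:, None, :, None] - mu**2
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv_std
    out_data = xhat.reshape(B, V, C) * gamma.data + beta.data

    def bw(gout):
        Tensor._accum(gamma, (gout * xhat.reshape(B, V, C)).sum(axis=(0, 1)))
        Tensor._accum(beta, gout.sum(axis=(0, 1)))
        dxhat = (gout * gamma.data).reshape(B, V, g, cg)
        m1 = np.einsum("bvgc->bg", dxhat)[:, None, :, None] / n
        m2 = np.einsum("bvgc,bvgc->bg", dxhat, xhat)[:, None, :, None] / n
        dx = inv_std * (dxhat - m1 - xhat * m2)
        Tensor._accum(x, dx.reshape(B, V, C).astype(np.float32, copy=False))

    out = Tensor(out_data)
    if _GRAD_ENABLED:
        out._prev = (x, gamma, beta)
        out._backward = bw
    return out


def concat(tensors: list, axis: int = -1) -> Tensor:
    """Concatenate tensors; gradient splits back to the inputs."""
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    widths = [t.shape[axis] for t in tensors]

    def bw(g):
        pieces = np.split(g, np.cumsum(widths)[:-1], axis=axis)
        for t, p in zip(tensors, pieces):
            Tensor._accum(t, p)

    out = Tensor(out_data)
    if _GRAD_ENABLED:
        out._prev = tuple(tensors)
        out._backward = bw
    return out


class Module:
    """Parameter container with recursive collection, torchless and tiny."""

    def parameters(self) -> list:
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint parameter shape mismatch")
            p.data = np.asarray(a, dtype=np.float32)


class Adam:
    """Adaptive-moment optimizer with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
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
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)
            if self.weight_decay and p.data.ndim > 1:  # decay weights, not biases/gains
                p.data = p.data * (1.0 - self.lr * self.weight_decay)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
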