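"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every tensor created with
``requires_grad=True``.  Only the operations the codec and classifier need are
implemented: broadcast arithmetic, matmul, shape ops, leaky-rectifier /
sigmoid / softmax nonlinearities, layer normalisation, strided convolution and
transposed convolution (via im2col/col2im), and the two losses (mean absolute
error, label-smoothed cross-entropy).

Every gradient here is checked against central finite differences in the test
suite; the graph machinery is deliberately simple (no in-place ops, no views).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad"]


class _NoGrad:
    """Context manager disabling graph construction (evaluation mode)."""

    _enabled = True

    def __enter__(self):
        self._prev = _NoGrad._enabled
        _NoGrad._enabled = False
        return self

    def __exit__(self, *exc):
        _NoGrad._enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _NoGrad._enabled and any(p.requires_grad or p._parents for p in parents):
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._coerce(other)

        def backward(g):
            ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
            gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return Tensor._make(np.matmul(self.data, other.data), (self, other), backward)

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return Tensor._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.shape

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearities ---------------------------------------------------
    def leaky_relu(self, slope: float = 0.01) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        return Tensor._make(s, (self,), lambda g: (g * s * (1.0 - s),))

    def abs(self) -> "Tensor":
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            return ((g - dot) * s,)

        return Tensor._make(s, (self,), backward)

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        """Normalise over the last axis; gamma/beta broadcast over it."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = xhat * gamma.data + beta.data
        d = x.shape[-1]

        def backward(g):
            dxhat = g * gamma.data
            dx = inv / d * (
                d * dxhat
                - dxhat.sum(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
            )
            axes = tuple(range(g.ndim - 1))
            return dx, (g * xhat).sum(axis=axes), g.sum(axis=axes)

        return Tensor._make(out, (self, gamma, beta), backward)

    # -- convolution ------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor | None",
               stride: int = 1, padding: int = 0) -> "Tensor":
        """2-D cross-correlation, NCHW layout, weight (O, C, k, k)."""
        x, w = self.data, weight.data
        out, cols, meta = _conv2d_forward(x, w, stride, padding)
        if bias is not None:
            out = out + bias.data[None, :, None, None]

        def backward(g):
            dx, dw = _conv2d_backward(g, x, w, cols, stride, padding, meta)
            db = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (dx, dw) + ((db,) if bias is not None else ())

        parents = (self, weight) + ((bias,) if bias is not None else ())
        return Tensor._make(out, parents, backward)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor | None",
                         stride: int = 1, padding: int = 0) -> "Tensor":
        """Transposed convolution (fractionally-strided), weight (C_in, C_out, k, k).

        Output spatial side: (S - 1) * stride - 2 * padding + k.
        """
        x, w = self.data, weight.data
        out = _convT_forward(x, w, stride, padding)
        if bias is not None:
            out = out + bias.data[None, :, None, None]

        def backward(g):
            dx, dw = _convT_backward(g, x, w, stride, padding)
            db = g.sum(axis=(0, 2, 3)) if bias is not None else None
            return (dx, dw) + ((db,) if bias is not None else ())

        parents = (self, weight) + ((bias,) if bias is not None else ())
        return Tensor._make(out, parents, backward)

    # -- losses -----------------------------------------------------------
    def mae(self, target: np.ndarray) -> "Tensor":
        """Mean absolute error against a constant target."""
        diff = self - Tensor(np.asarray(target, dtype=np.float64))
        return diff.abs().mean()

    def cross_entropy(self, labels: np.ndarray, label_smoothing: float = 0.0,
                      class_weights: np.ndarray | None = None) -> "Tensor":
        """Softmax cross-entropy of logits (N, K) against integer labels (N,).

        Label smoothing spreads ``label_smoothing`` of the target mass
        uniformly over all classes.  Optional per-class weights rescale each
        sample's loss by the weight of its true class.
        """
        logits = self.data
        n, k = logits.shape
        labels = np.asarray(labels, dtype=np.int64)
        t = np.full((n, k), label_smoothing / k)
        t[np.arange(n), labels] += 1.0 - label_smoothing
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        if class_weights is not None:
            wvec = np.asarray(class_weights, dtype=np.float64)[labels]
        else:
            wvec = np.ones(n)
        wnorm = wvec / wvec.sum()
        loss = -(wnorm[:, None] * t * logp).sum()
        p = np.exp(logp)

        def backward(g):
            return (g * wnorm[:, None] * (p - t),)

        return Tensor._make(loss, (self,), backward)


# ---------------------------------------------------------------------------
# im2col / col2im convolution kernels
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, padding: int):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - k) // stride + 1
    wo = (w + 2 * padding - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, k, k)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, padding: int,
            ho: int, wo: int) -> np.ndarray:
    n, c, h, w = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    out = np.zeros((n, c, hp, wp))
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols[:, :, i, j]
            )
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def _conv2d_forward(x, w, stride, padding):
    o, c, k, _ = w.shape
    cols, ho, wo = _im2col(x, k, stride, padding)
    out = np.matmul(w.reshape(o, -1), cols).reshape(x.shape[0], o, ho, wo)
    return out, cols, (ho, wo)


def _conv2d_backward(g, x, w, cols, stride, padding, meta):
    ho, wo = meta
    n = x.shape[0]
    o, c, k, _ = w.shape
    gr = g.reshape(n, o, ho * wo)
    dw = np.tensordot(gr, cols, axes=([0, 2], [0, 2])).reshape(w.shape)
    dcols = np.matmul(w.reshape(o, -1).T, gr)
    dx = _col2im(dcols, x.shape, k, stride, padding, ho, wo)
    return dx, dw


def _convT_forward(x, w, stride, padding):
    # convT(x; w) == input-gradient of conv with weight w viewed as (C_in, C_out, k, k)
    n, cin, h, wdt = x.shape
    _, cout, k, _ = w.shape
    ho = (h - 1) * stride - 2 * padding + k
    wo = (wdt - 1) * stride - 2 * padding + k
    xr = x.reshape(n, cin, h * wdt)
    dcols = np.matmul(w.reshape(cin, -1).T, xr)  # (n, cout*k*k, h*w)
    return _col2im(dcols, (n, cout, ho, wo), k, stride, padding, h, wdt)


def _convT_backward(g, x, w, stride, padding):
    n, cin, h, wdt = x.shape
    _, cout, k, _ = w.shape
    cols, ho2, wo2 = _im2col(g, k, stride, padding)  # ho2 == h, wo2 == wdt
    dx = np.matmul(w.reshape(cin, -1), cols).reshape(x.shape)
    xr = x.reshape(n, cin, h * wdt)
    dw = np.tensordot(xr, cols, axes=([0, 2], [0, 2])).reshape(w.shape)
    return dx, dw
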