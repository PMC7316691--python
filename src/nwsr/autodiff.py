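"""Minimal reverse-mode automatic differentiation on numpy arrays.

This module provides exactly the operations needed by the trainable
Nadaraya-Watson layer, the convolutional super-resolution networks and the
differentiable SSIM+L1 objective: broadcast-aware elementwise arithmetic,
``abs``/``relu``, reductions, reshape and a zero-padded 2-D cross-correlation
(``conv2d``). Gradients are accumulated through a tape built dynamically as
operations execute; calling :meth:`Tensor.backward` on a scalar result fills
``.grad`` on every reachable tensor with ``requires_grad=True``.

All data is kept in float64: the networks here are small and the package's
test oracles (finite-difference gradient checks, brute-force convolution
sums) are compared at tolerances that single precision would not meet.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "conv2d", "relu", "absolute", "concat_channels"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
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
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph machinery -----------------------------------------------------
    def _needs_graph(self) -> bool:
        return self.requires_grad or self._parents != ()

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float64)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs would blow the recursion limit
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

        grads: dict[int, np.ndarray] = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent._needs_graph():
                    continue
                pid = id(parent)
                if pid in grads:
                    grads[pid] = grads[pid] + pg
                else:
                    grads[pid] = pg

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: (_unbroadcast(g, a.shape),
                                        _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: (_unbroadcast(g, a.shape),
                                        _unbroadcast(-g, b.shape)))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: (_unbroadcast(g * b, a.shape),
                                        _unbroadcast(g * a, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide,
                       lambda g, a, b: (_unbroadcast(g / b, a.shape),
                                        _unbroadcast(-g * a / (b * b), b.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p):
        if p != 2:
            raise NotImplementedError("only squaring is supported")
        return self * self

    # -- shaping and reductions ----------------------------------------------
    def reshape(self, *shape):
        out = _node(np.reshape(self.data, shape), (self,))
        src_shape = self.data.shape
        out._backward = lambda g: (g.reshape(src_shape),)
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape = self.data.shape

        def back(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, shape).copy(),)

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple) -> Tensor:
    out = Tensor(data)
    if any(p._needs_graph() for p in parents):
        out._parents = parents
    return out


def _binary(a, b, fwd, bwd) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _node(fwd(a.data, b.data), (a, b))
    if out._parents:
        out._backward = lambda g: bwd(g, a.data, b.data)
    return out


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(np.abs(x.data), (x,))
    if out._parents:
        sign = np.sign(x.data)
        out._backward = lambda g: (g * sign,)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(np.maximum(x.data, 0.0), (x,))
    if out._parents:
        gate = (x.data > 0.0).astype(np.float64)
        out._backward = lambda g: (g * gate,)
    return out


def concat_channels(tensors) -> Tensor:
    """Concatenate (N, C, H, W) tensors along the channel axis."""
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors))
    if out._parents:
        splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

        def back(g):
            return tuple(np.split(g, splits, axis=1))

        out._backward = back
    return out


# ---------------------------------------------------------------------------
# 2-D cross-correlation
# ---------------------------------------------------------------------------

#: Kernels with at least this many taps go through the FFT path.
_FFT_TAPS = 27


def _corr_raw(x: np.ndarray, w: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Cross-correlate (N,C,H,W) with (T,C,kh,kw), zero padding (ph, pw).

    Small kernels accumulate one matmul per tap over contiguous shifted
    slices (much faster in numpy than materialising an im2col matrix);
    large kernels switch to FFT convolution.
    """
    n, c, _, _ = x.shape
    t, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input has {c}, kernels expect {c2}")
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = xp.shape[2] - kh + 1
    wo = xp.shape[3] - kw + 1
    if kh * kw >= _FFT_TAPS:
        from scipy.signal import fftconvolve
        full = fftconvolve(xp[:, None], w[None, :, :, ::-1, ::-1],
                           axes=(3, 4)).sum(axis=2)
        return np.ascontiguousarray(full[:, :, kh - 1:kh - 1 + ho,
                                         kw - 1:kw - 1 + wo])
    out = np.zeros((n, t, ho * wo))
    for i in range(kh):
        for j in range(kw):
            tap = w[:, :, i, j]
            if not tap.any():
                continue
            xs = np.ascontiguousarray(xp[:, :, i:i + ho, j:j + wo]).reshape(n, c, -1)
            out += tap @ xs
    return out.reshape(n, t, ho, wo)


def _corr_grad_w(x: np.ndarray, go: np.ndarray, kh: int, kw: int,
                 ph: int, pw: int) -> np.ndarray:
    """Gradient of :func:`_corr_raw` with respect to the kernel bank."""
    n, c, _, _ = x.shape
    t = go.shape[1]
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho, wo = go.shape[2], go.shape[3]
    if kh * kw >= _FFT_TAPS:
        from scipy.signal import fftconvolve
        full = fftconvolve(xp[:, :, None], go[:, None, :, ::-1, ::-1],
                           axes=(3, 4)).sum(axis=0)
        return np.ascontiguousarray(
            full[:, :, ho - 1:ho - 1 + kh, wo - 1:wo - 1 + kw].transpose(1, 0, 2, 3))
    go_flat = np.ascontiguousarray(go.transpose(1, 0, 2, 3)).reshape(t, -1)
    grad_w = np.empty((t, c, kh, kw))
    for i in range(kh):
        for j in range(kw):
            xs = np.ascontiguousarray(
                xp[:, :, i:i + ho, j:j + wo].transpose(1, 0, 2, 3)).reshape(c, -1)
            grad_w[:, :, i, j] = go_flat @ xs.T
    return grad_w


def conv2d(x, w, bias=None, padding: int = 0) -> Tensor:
    """Zero-padded 2-D cross-correlation of (N,C,H,W) with a (T,C,kh,kw) bank.

    `padding` may be an int (both axes) or an (ph, pw) pair. With
    padding = k and odd kernels 2k+1, the spatial size is preserved.
    """
    x, w = as_tensor(x), as_tensor(w)
    if x.ndim != 4 or w.ndim != 4:
        raise ValueError("conv2d expects x as (N,C,H,W) and w as (T,C,kh,kw)")
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    t, c, kh, kw = w.data.shape
    out_data = _corr_raw(x.data, w.data, ph, pw)
    if bias is not None:
        bias = as_tensor(bias)
        out_data = out_data + bias.data.reshape(1, -1, 1, 1)
        parents = (x, w, bias)
    else:
        parents = (x, w)
    out = _node(out_data, parents)
    if not out._parents:
        return out

    n, _, h, w_in = x.data.shape
    w_flip = np.ascontiguousarray(
        w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))  # (C, T, kh, kw)

    def back(g):
        g = np.ascontiguousarray(g)
        grad_w = None
        grad_x = None
        if w._needs_graph():
            grad_w = _corr_grad_w(x.data, g, kh, kw, ph, pw)
        if x._needs_graph():
            gx_p = _corr_raw(g, w_flip, kh - 1, kw - 1)
            grad_x = gx_p[:, :, ph:ph + h, pw:pw + w_in]
        if bias is not None:
            return grad_x, grad_w, g.sum(axis=(0, 2, 3))
        return grad_x, grad_w

    out._backward = back
    return out
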