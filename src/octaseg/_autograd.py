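"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: each operation returns a new
:class:`Tensor` holding a closure that scatters the upstream gradient to its
inputs.  Convolutions are evaluated tap by tap as batched BLAS matmuls
(for a k x k kernel, k^2 shifted views of the padded input hit a
(C_out, C_in) weight slice each), which avoids im2col layout shuffles and
makes 1x1 convolutions a single gemm.  Everything is float32 and CPU-only;
stride is always 1 and padding is always "same", which is all a
full-resolution segmentation network needs.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterable

import numpy as np
from scipy import special

_GRAD_ENABLED = True

_INV_SQRT2 = 1.0 / math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block (inference)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An n-d float32 array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._children: tuple[Tensor, ...] = ()
        self._backward = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def size(self) -> int:
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray, fresh: bool = False) -> None:
        """Add ``g`` to the stored gradient.

        ``fresh=True`` promises ``g`` is a newly allocated float32 array no
        one else references, so it may be adopted without a defensive copy.
        """
        if self.grad is None:
            if fresh and isinstance(g, np.ndarray) and g.dtype == np.float32:
                self.grad = g
            else:
                self.grad = np.array(g, dtype=np.float32)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse sweep from this tensor; accumulates into ``.grad``."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: deep graphs (recursion, 4 stages) blow
            node, processed = stack.pop()  # the interpreter's recursion limit
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._children:
                if id(child) not in seen:
                    stack.append((child, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                node._backward = None
                node._children = ()
                if node is not self:
                    node.grad = None   # intermediate: free once propagated

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, mul_scalar(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul_scalar(self, -1.0))

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, float(other))
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul_scalar(self, 1.0 / float(other))
        return div(self, other)

    def __pow__(self, p: float):
        return power(self, p)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _finish(out: Tensor, children: tuple[Tensor, ...], backward) -> Tensor:
    if _GRAD_ENABLED and any(c.requires_grad for c in children):
        out.requires_grad = True
        out._children = children
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / reduction primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data)

    def _backward():
        g = out.grad
        if a.requires_grad:
            ga = _unbroadcast(g, a.shape)
            a._accum(ga, fresh=ga is not g)
        if b.requires_grad:
            gb = _unbroadcast(g, b.shape)
            # when gb aliases g, the buffer is exclusively this node's and a
            # already took a copy above, so b may adopt it outright
            b._accum(gb, fresh=True)

    return _finish(out, (a, b), _backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data)

    def _backward():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad * b.data, a.shape), fresh=True)
        if b.requires_grad:
            b._accum(_unbroadcast(out.grad * a.data, b.shape), fresh=True)

    return _finish(out, (a, b), _backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    out = Tensor(a.data * np.float32(s))

    def _backward():
        a._accum(out.grad * np.float32(s), fresh=True)

    return _finish(out, (a,), _backward)


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data)

    def _backward():
        if a.requires_grad:
            a._accum(_unbroadcast(out.grad / b.data, a.shape), fresh=True)
        if b.requires_grad:
            b._accum(_unbroadcast(-out.grad * a.data / (b.data * b.data), b.shape),
                     fresh=True)

    return _finish(out, (a, b), _backward)


def power(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data ** np.float32(p))

    def _backward():
        a._accum(out.grad * np.float32(p) * a.data ** np.float32(p - 1.0), fresh=True)

    return _finish(out, (a,), _backward)


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data))

    def _backward():
        a._accum(out.grad * out.data, fresh=True)

    return _finish(out, (a,), _backward)


def sqrt(a: Tensor, eps: float = 0.0) -> Tensor:
    """Square root; ``eps`` keeps the derivative finite at zero."""
    out = Tensor(np.sqrt(a.data + np.float32(eps)))

    def _backward():
        a._accum(out.grad * 0.5 / np.maximum(out.data, np.float32(1e-12)), fresh=True)

    return _finish(out, (a,), _backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims))

    def _backward():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.shape).astype(np.float32), fresh=True)

    return _finish(out, (a,), _backward)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul_scalar(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tmax(a: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Max along one axis; ties share the upstream gradient evenly."""
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data)
    mask = mask / mask.sum(axis=axis, keepdims=True)
    out = Tensor(out_data if keepdims else np.squeeze(out_data, axis=axis))

    def _backward():
        g = out.grad if keepdims else np.expand_dims(out.grad, axis)
        a._accum((mask * g).astype(np.float32), fresh=True)

    return _finish(out, (a,), _backward)


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0))

    def _backward():
        a._accum(out.grad * (a.data > 0), fresh=True)

    return _finish(out, (a,), _backward)


def sigmoid(a: Tensor) -> Tensor:
    out = Tensor(special.expit(a.data))

    def _backward():
        a._accum(out.grad * out.data * (1.0 - out.data), fresh=True)

    return _finish(out, (a,), _backward)


def gelu(a: Tensor) -> Tensor:
    """Exact (erf) GeLU."""
    phi = 0.5 * (1.0 + special.erf(a.data * _INV_SQRT2))
    out = Tensor(a.data * phi)

    def _backward():
        pdf = _INV_SQRT_2PI * np.exp(-0.5 * a.data * a.data)
        a._accum((out.grad * (phi + a.data * pdf)).astype(np.float32), fresh=True)

    return _finish(out, (a,), _backward)


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape))

    def _backward():
        # out.grad's buffer is exclusive to this node; the reshaped view (or
        # copy) may be adopted by the single parent
        a._accum(out.grad.reshape(a.shape), fresh=True)

    return _finish(out, (a,), _backward)


def concat(tensors: Iterable[Tensor], axis: int) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in ts], axis=axis))
    sizes = [t.shape[axis] for t in ts]

    def _backward():
        pieces = np.split(out.grad, np.cumsum(sizes)[:-1], axis=axis)
        for t, g in zip(ts, pieces):
            if t.requires_grad:
                t._accum(g, fresh=True)   # disjoint views of an exclusive buffer

    return _finish(out, tuple(ts), _backward)


def getitem(a: Tensor, idx) -> Tensor:
    out = Tensor(a.data[idx])

    def _backward():
        g = np.zeros_like(a.data)
        g[idx] = out.grad
        a._accum(g, fresh=True)

    return _finish(out, (a,), _backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data)

    def _backward():
        if a.requires_grad:
            a._accum(out.grad @ b.data.T, fresh=True)
        if b.requires_grad:
            b._accum(a.data.T @ out.grad, fresh=True)

    return _finish(out, (a, b), _backward)


def norm_affine(x: Tensor, w: Tensor, b: Tensor, axes: tuple[int, ...],
                eps: float) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused ``(x - mean) / sqrt(var + eps) * w + b`` over the given axes.

    One primitive serves both batch norm (axes over batch and space) and the
    channelwise layer norm of ConvNeXt-style trunks (axis 1).  ``w`` and
    ``b`` must already be broadcast-shaped.  Returns the output together
    with the (keepdims) batch mean and variance so batch-norm layers can
    maintain running statistics.  The backward pass is the standard
    whitening gradient:

        dx = (g*w - mean(g*w) - xhat * mean(g*w * xhat)) / sqrt(var + eps)
    """
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + np.float32(eps))
    xhat = xc * inv
    out = Tensor(xhat * w.data + b.data)

    def _backward():
        g = out.grad
        if w.requires_grad:
            w._accum(_unbroadcast(g * xhat, w.shape), fresh=True)
        if b.requires_grad:
            gb = _unbroadcast(g, b.shape)
            b._accum(gb, fresh=gb is not g)
        if x.requires_grad:
            gh = g * w.data
            m1 = gh.mean(axis=axes, keepdims=True)
            m2 = (gh * xhat).mean(axis=axes, keepdims=True)
            x._accum(((gh - m1 - xhat * m2) * inv).astype(np.float32, copy=False),
                     fresh=True)

    return _finish(out, (x, w, b), _backward), mu, var


# ---------------------------------------------------------------------------
# convolutions (stride 1, "same" padding)
# ---------------------------------------------------------------------------

def _same_pad(k: int, dilation: int) -> int:
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd for 'same' padding, got {k}")
    return dilation * (k - 1) // 2


def _pad_spatial(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))


def _conv_fwd(x: np.ndarray, w: np.ndarray, dilation: int
              ) -> tuple[np.ndarray, np.ndarray]:
    """Tap-wise forward: y[n,o,p] = sum_ij W[o,:,i,j] @ x_shift(i,j)[n,:,p]."""
    n, c, h, wd = x.shape
    cout, _, k, _ = w.shape
    if k == 1:
        y = np.matmul(w[:, :, 0, 0], x.reshape(n, c, h * wd))
        return y.reshape(n, cout, h, wd), x
    p = _same_pad(k, dilation)
    xp = _pad_spatial(x, p)
    y = np.zeros((n, cout, h * wd), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i * dilation:i * dilation + h,
                    j * dilation:j * dilation + wd].reshape(n, c, h * wd)
            y += np.matmul(w[:, :, i, j], xs)
    return y.reshape(n, cout, h, wd), xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1) -> Tensor:
    """Standard cross-correlation, stride 1, same padding.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, k, k); ``b``: (Cout,) or None.
    """
    if x.shape[1] != w.shape[1]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"kernel expects {w.shape[1]}"
        )
    y, xp = _conv_fwd(x.data, w.data, dilation)
    if b is not None:
        y += b.data[None, :, None, None]
    out = Tensor(y)
    children = (x, w) if b is None else (x, w, b)

    def _backward():
        n, cout, h, wd = out.grad.shape
        cin, k = w.shape[1], w.shape[-1]
        gy = out.grad.reshape(n, cout, h * wd)
        if b is not None and b.requires_grad:
            b._accum(out.grad.sum(axis=(0, 2, 3)), fresh=True)
        if k == 1:
            if w.requires_grad:
                xs = xp.reshape(n, cin, h * wd)
                dw = np.matmul(gy, xs.transpose(0, 2, 1)).sum(axis=0)
                w._accum(dw.reshape(w.shape), fresh=True)
            if x.requires_grad:
                dx = np.matmul(w.data[:, :, 0, 0].T, gy)
                x._accum(dx.reshape(x.shape), fresh=True)
            return
        p = _same_pad(k, dilation)
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(k):
            for j in range(k):
                sl = (slice(None), slice(None),
                      slice(i * dilation, i * dilation + h),
                      slice(j * dilation, j * dilation + wd))
                if dw is not None:
                    xs = xp[sl].reshape(n, cin, h * wd)
                    dw[:, :, i, j] = np.matmul(
                        gy, xs.transpose(0, 2, 1)).sum(axis=0)
                if need_dx:
                    dxs = np.matmul(w.data[:, :, i, j].T, gy)
                    dxp[sl] += dxs.reshape(n, cin, h, wd)
        if dw is not None:
            w._accum(dw, fresh=True)
        if need_dx:
            dx = dxp[:, :, p:p + h, p:p + wd] if p else dxp
            x._accum(np.ascontiguousarray(dx), fresh=True)

    return _finish(out, children, _backward)


def _dilate_kernel(w: np.ndarray, dilation: int) -> np.ndarray:
    """(C, k, k) -> (C, span, span) with taps spaced ``dilation`` apart."""
    if dilation == 1:
        return w
    c, k, _ = w.shape
    span = dilation * (k - 1) + 1
    wd = np.zeros((c, span, span), dtype=w.dtype)
    wd[:, ::dilation, ::dilation] = w
    return wd


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, dilation: int = 1) -> Tensor:
    """Per-channel cross-correlation. ``w``: (C, k, k); ``b``: (C,) or None.

    Evaluated in the Fourier domain, batched over (N, C): per-channel
    correlation is a plain product there, which beats spatial tap loops for
    the 7x7 trunk kernels.  With FFT size (H + span - 1, W + span - 1) the
    circular products below reproduce the linear results exactly:

    * forward: ``y = conv(x, flip(W))`` read off at offset ``p`` (same
      padding, ``p = (span - 1) / 2``);
    * input gradient: ``dx = conv(gy, W)`` at the same offset;
    * weight gradient: ``dW[t] = sum_u gy[u] x[u + t]`` for lags
      ``t in [-p, p]``, i.e. ``irfft(conj(F_gy) * F_x)`` — the wrapped lag
      reads land in the zero padding, so no aliasing enters.
    """
    if x.shape[1] != w.shape[0]:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"depthwise kernel has {w.shape[0]}"
        )
    from scipy import fft as _fft

    n, c, h, wd_ = x.shape
    k = w.shape[-1]
    _same_pad(k, dilation)  # validates odd kernel size
    wdil = _dilate_kernel(w.data, dilation)
    span = wdil.shape[-1]
    p = span // 2
    fsz = (h + span - 1, wd_ + span - 1)
    Fx = _fft.rfft2(x.data, s=fsz, axes=(2, 3))
    Fw_flip = _fft.rfft2(wdil[:, ::-1, ::-1], s=fsz, axes=(1, 2))
    y = _fft.irfft2(Fx * Fw_flip[None], s=fsz, axes=(2, 3))
    y = np.ascontiguousarray(y[:, :, p:p + h, p:p + wd_], dtype=np.float32)
    if b is not None:
        y += b.data[None, :, None, None]
    out = Tensor(y)
    children = (x, w) if b is None else (x, w, b)

    def _backward():
        gy = out.grad
        if b is not None and b.requires_grad:
            b._accum(gy.sum(axis=(0, 2, 3)), fresh=True)
        Fg = _fft.rfft2(gy, s=fsz, axes=(2, 3))
        if w.requires_grad:
            corr = _fft.irfft2((np.conj(Fg) * Fx).sum(axis=0), s=fsz, axes=(1, 2))
            lags = np.arange(-p, p + 1) % fsz[0]
            lags_w = np.arange(-p, p + 1) % fsz[1]
            dwd = corr[:, lags][:, :, lags_w]          # (C, span, span)
            if dilation > 1:
                dwd = dwd[:, ::dilation, ::dilation]
            w._accum(np.ascontiguousarray(dwd, dtype=np.float32), fresh=True)
        if x.requires_grad:
            Fw = _fft.rfft2(wdil, s=fsz, axes=(1, 2))
            dx = _fft.irfft2(Fg * Fw[None], s=fsz, axes=(2, 3))
            x._accum(np.ascontiguousarray(
                dx[:, :, p:p + h, p:p + wd_], dtype=np.float32), fresh=True)

    return _finish(out, children, _backward)
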