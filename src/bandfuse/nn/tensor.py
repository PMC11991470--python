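"""A small tape-based automatic-differentiation engine on NumPy arrays.

This module provides exactly the primitives the package's architectures
need: elementwise arithmetic with broadcasting, (batched) matmul,
reshape/transpose/concatenate, ReLU/Tanh/exp/log/pow, axis reductions,
softmax, cross-entropy, 2-D and 3-D convolution (stride-1 3-D), depthwise
convolution, max pooling and adaptive average pooling.  Gradients are
accumulated by reverse-mode sweep over a dynamically recorded tape.

Everything is plain float32 NumPy, so runs are bit-reproducible on a
fixed machine for a fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "cross_entropy", "conv2d",
           "depthwise_conv2d", "conv3d", "maxpool_hw", "maxpool2d",
           "maxpool2d_3x3s1", "adaptive_avg_pool_hw"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------
    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Reverse sweep from this tensor (defaults to d(self)/d(self)=1)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.ones_like(self.data) if grad is None
                    else np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return Tensor._from_op(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._from_op(out_data, (self, other), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return Tensor._from_op(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a: int, b: int):
        axes = list(range(self.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- elementwise nonlinearities ---------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def relu6(self):
        out_data = np.clip(self.data, 0.0, 6.0)
        mask = (self.data > 0) & (self.data < 6)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._from_op(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data ** 2))

        return Tensor._from_op(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return Tensor._from_op(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if not self.requires_grad:
                return
            gg = g
            if not keepdims and axis is not None:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(a % len(shape) for a in axes)
                for a in sorted(axes):
                    gg = np.expand_dims(gg, a)
            self._accum(np.broadcast_to(gg, shape).astype(np.float32))

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, s, e in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(s, e)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(out_data, tuple(tensors), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    s = np.exp(z)
    s /= s.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            x._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor._from_op(s, (x,), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under row softmax."""
    y = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(lse - z[np.arange(n), y]))

    def backward(g):
        if logits.requires_grad:
            p = np.exp(z)
            p /= p.sum(axis=1, keepdims=True)
            p[np.arange(n), y] -= 1.0
            logits._accum(p * (g / n))

    return Tensor._from_op(np.float32(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# Convolution / pooling primitives
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    pads = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    return np.pad(x, pads)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """2-D cross-correlation; x (N,C,H,W), w (F,C,kh,kw) -> (N,F,Ho,Wo)."""
    N, C, H, W = x.data.shape
    F, _, kh, kw = w.data.shape
    xp = _pad_hw(x.data, padding)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # (N,C,Ho,Wo,kh,kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N, Ho * Wo, C * kh * kw)
    wmat = w.data.reshape(F, -1)
    out = cols @ wmat.T                                     # (N,HoWo,F)
    if b is not None:
        out += b.data
    out_data = out.transpose(0, 2, 1).reshape(N, F, Ho, Wo)

    def backward(g):
        gmat = g.reshape(N, F, Ho * Wo).transpose(0, 2, 1)  # (N,HoWo,F)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("npf,npk->fk", gmat, cols, optimize=True)
            w._accum(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, :, di:di + stride * Ho:stride,
                        dj:dj + stride * Wo:stride] += dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out_data, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
                     padding: int = 0) -> Tensor:
    """Per-channel convolution; x (N,C,H,W), w (C,kh,kw) -> (N,C,Ho,Wo)."""
    N, C, H, W = x.data.shape
    _, kh, kw = w.data.shape
    xp = _pad_hw(x.data, padding)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - kh) // stride + 1
    Wo = (Wp - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                     # (N,C,Ho,Wo,kh,kw)
    out_data = np.einsum("nchwij,cij->nchw", win, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accum(np.einsum("nchw,nchwij->cij", g, win, optimize=True))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for di in range(kh):
                for dj in range(kw):
                    dxp[:, :, di:di + stride * Ho:stride,
                        dj:dj + stride * Wo:stride] += g * w.data[None, :, di, dj, None, None]
            if padding:
                dxp = dxp[:, :, padding:padding + H, padding:padding + W]
            x._accum(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out_data, parents, backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, padding: int = 1) -> Tensor:
    """Stride-1 3-D cross-correlation; x (N,C,D,H,W), w (F,C,kd,kh,kw)."""
    N, C, D, H, W = x.data.shape
    F, _, kd, kh, kw = w.data.shape
    p = padding
    xp = np.pad(x.data, [(0, 0), (0, 0), (p, p), (p, p), (p, p)])
    Do, Ho, Wo = D + 2 * p - kd + 1, H + 2 * p - kh + 1, W + 2 * p - kw + 1
    out = np.zeros((N, F, Do, Ho, Wo), dtype=np.float32)
    slabs = {}
    for dd in range(kd):
        for di in range(kh):
            for dj in range(kw):
                xs = xp[:, :, dd:dd + Do, di:di + Ho, dj:dj + Wo]
                slabs[(dd, di, dj)] = xs
                out += np.einsum("ncdhw,fc->nfdhw", xs, w.data[:, :, dd, di, dj],
                                 optimize=True)
    if b is not None:
        out += b.data[None, :, None, None, None]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for (dd, di, dj), xs in slabs.items():
            if w.requires_grad:
                dw = np.einsum("nfdhw,ncdhw->fc", g, xs, optimize=True)
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[:, :, dd, di, dj] += dw
            if dxp is not None:
                dxp[:, :, dd:dd + Do, di:di + Ho, dj:dj + Wo] += np.einsum(
                    "nfdhw,fc->ncdhw", g, w.data[:, :, dd, di, dj], optimize=True)
        if dxp is not None:
            x._accum(dxp[:, :, p:p + D, p:p + H, p:p + W] if p else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._from_op(out, parents, backward)


def maxpool_hw(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k max pooling over the last two axes (any ndim)."""
    shape = x.data.shape
    H, W = shape[-2:]
    if H % k or W % k:
        raise ValueError(f"spatial size {H}x{W} not divisible by pool size {k}")
    Ho, Wo = H // k, W // k
    lead = shape[:-2]
    xr = x.data.reshape(*lead, Ho, k, Wo, k)
    xr = np.moveaxis(xr, -3, -2).reshape(*lead, Ho, Wo, k * k)
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxr = np.zeros((*lead, Ho, Wo, k * k), dtype=np.float32)
        np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
        dxr = np.moveaxis(dxr.reshape(*lead, Ho, Wo, k, k), -2, -3)
        x._accum(dxr.reshape(shape))

    return Tensor._from_op(out_data, (x,), backward)


def maxpool2d(x: Tensor, k: int, stride: int | None = None,
              padding: int = 0) -> Tensor:
    """General max pooling over the last two axes of a 4-D tensor."""
    stride = stride or k
    N, C, H, W = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, [(0, 0), (0, 0), (padding, padding), (padding, padding)],
                    constant_values=-np.inf)
    Hp, Wp = xp.shape[2:]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(N, C, Ho, Wo, k * k)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((N, C, Hp, Wp), dtype=np.float32)
        di, dj = np.divmod(idx, k)
        ii = np.arange(Ho)[None, None, :, None] * stride + di
        jj = np.arange(Wo)[None, None, None, :] * stride + dj
        nn_, cc = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
        np.add.at(dxp, (nn_[:, :, None, None], cc[:, :, None, None], ii, jj), g)
        if padding:
            dxp = dxp[:, :, padding:padding + H, padding:padding + W]
        x._accum(dxp)

    return Tensor._from_op(out_data, (x,), backward)


def maxpool2d_3x3s1(x: Tensor) -> Tensor:
    """3×3, stride-1, pad-1 max pooling (the inception pool branch)."""
    N, C, H, W = x.data.shape
    xp = np.pad(x.data, [(0, 0), (0, 0), (1, 1), (1, 1)],
                constant_values=-np.inf)
    stack = np.stack([xp[:, :, di:di + H, dj:dj + W]
                      for di in range(3) for dj in range(3)])
    idx = stack.argmax(axis=0)
    out_data = np.take_along_axis(stack, idx[None], axis=0)[0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((N, C, H + 2, W + 2), dtype=np.float32)
        for o in range(9):
            di, dj = divmod(o, 3)
            mask = idx == o
            dxp[:, :, di:di + H, dj:dj + W] += g * mask
        x._accum(dxp[:, :, 1:1 + H, 1:1 + W])

    return Tensor._from_op(out_data, (x,), backward)


def adaptive_avg_pool_hw(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Adaptive average pooling over the last two axes to a fixed grid.

    Bin *i* of an axis of length L covers [floor(iL/o), ceil((i+1)L/o)),
    so any input at least as large as the output grid is supported.
    """
    oh, ow = out_hw
    shape = x.data.shape
    H, W = shape[-2:]
    if H < oh or W < ow:
        raise ValueError(f"input {H}x{W} smaller than target grid {oh}x{ow}")
    lead = shape[:-2]
    out_data = np.empty((*lead, oh, ow), dtype=np.float32)
    bins = []
    for i in range(oh):
        si, ei = (i * H) // oh, -(-((i + 1) * H) // oh)
        for j in range(ow):
            sj, ej = (j * W) // ow, -(-((j + 1) * W) // ow)
            bins.append((i, j, si, ei, sj, ej))
            out_data[..., i, j] = x.data[..., si:ei, sj:ej].mean(axis=(-1, -2))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros(shape, dtype=np.float32)
        for i, j, si, ei, sj, ej in bins:
            area = (ei - si) * (ej - sj)
            dx[..., si:ei, sj:ej] += g[..., i, j, None, None] / area
        x._accum(dx)

    return Tensor._from_op(out_data, (x,), backward)
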