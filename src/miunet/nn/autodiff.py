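"""Reverse-mode automatic differentiation over numpy arrays.

A minimal tape-based engine sized for small 2D convolutional networks: a
:class:`Tensor` wraps an ``ndarray`` and records, per operation, a closure
that accumulates gradients into its parents.  Convolutions are evaluated as
a single GEMM over an ``as_strided`` im2col view, which keeps the per-step
cost dominated by BLAS even on one CPU core.

Only the operations the segmentation networks and their losses need are
implemented; everything is exact (no approximation in any backward rule),
so analytic gradients can be validated against central differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .._exceptions import DimensionError

__all__ = ["Tensor", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            # own the buffer: closures may hand us views of larger arrays
            self.grad = np.array(grad, dtype=grad.dtype)
        else:
            self.grad += grad

    def backward(self, grad=None):
        """Backpropagate from this node (scalar by default)."""
        if grad is None:
            if self.data.size != 1:
                raise DimensionError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order, iterative to avoid recursion limits
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        out_data = a.data ** e

        def backward(g):
            if a.requires_grad:
                a._accum(g * e * a.data ** (e - 1.0))

        return Tensor._make(out_data, (a,), backward)

    # -- elementwise ------------------------------------------------------

    def log(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * sign)

        return Tensor._make(np.abs(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is zero where the clamp is active."""
        a = self
        inside = (a.data > lo) & (a.data < hi)

        def backward(g):
            if a.requires_grad:
                a._accum(g * inside)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # -- reductions & reshapes -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        orig = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return Tensor._make(a.data.reshape(*shape), (a,), backward)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def backward(g):
            if a.requires_grad:
                a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, idx, g)
                a._accum(full)

        return Tensor._make(a.data[idx], (a,), backward)

    # -- softmax ----------------------------------------------------------

    def softmax(self, axis: int = 1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        ez = np.exp(z)
        y = ez / ez.sum(axis=axis, keepdims=True)

        def backward(g):
            if a.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))

        return Tensor._make(y, (a,), backward)

    def batchnorm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Fused per-channel batch normalization over (N, H, W).

        Returns (out, batch_mean, batch_var) with the statistics as plain
        arrays for running-average updates. Single-pass backward rule.
        """
        a, gm, bt = self, gamma, beta
        x = a.data
        n, c = x.shape[0], x.shape[1]
        m = x.size // c  # elements per channel
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
        out = xhat * gm.data.reshape(1, c, 1, 1) + bt.data.reshape(1, c, 1, 1)

        def backward(g):
            gsum = g.sum(axis=(0, 2, 3))
            gx_sum = (g * xhat).sum(axis=(0, 2, 3))
            if bt.requires_grad:
                bt._accum(gsum.astype(bt.dtype))
            if gm.requires_grad:
                gm._accum(gx_sum.astype(gm.dtype))
            if a.requires_grad:
                coef = (gm.data * inv_std / m).reshape(1, c, 1, 1)
                a._accum(
                    coef
                    * (
                        m * g
                        - gsum.reshape(1, c, 1, 1)
                        - xhat * gx_sum.reshape(1, c, 1, 1)
                    )
                )

        return Tensor._make(out, (a, gm, bt), backward), mu, var

    # -- spatial operations (NCHW) ----------------------------------------

    def conv2d(self, weight: "Tensor", bias: "Tensor", padding: int):
        """Stride-1 cross-correlation; weight is (Cout, Cin, k, k)."""
        a, w, b = self, weight, bias
        x = a.data
        if x.ndim != 4 or w.data.ndim != 4 or x.shape[1] != w.shape[1]:
            raise DimensionError(
                f"conv2d expects NCHW input matching weight Cin; got {x.shape} vs {w.shape}"
            )
        n, cin, h, wd = x.shape
        cout, _, k, _ = w.shape
        xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho, wo = h + 2 * padding - k + 1, wd + 2 * padding - k + 1
        s = xp.strides
        cols = as_strided(
            xp, (n, cin, k, k, ho, wo), (s[0], s[1], s[2], s[3], s[2], s[3])
        ).reshape(n, cin * k * k, ho * wo)
        wm = w.data.reshape(cout, cin * k * k)
        out = np.matmul(wm[None], cols).reshape(n, cout, ho, wo)
        out += b.data.reshape(1, cout, 1, 1)

        def backward(g):
            gm = g.reshape(n, cout, ho * wo)
            if b.requires_grad:
                b._accum(gm.sum(axis=(0, 2)))
            if w.requires_grad:
                gw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
                w._accum(gw.reshape(w.shape))
            if a.requires_grad:
                dcols = np.matmul(wm.T[None], gm)  # n, cin*k*k, ho*wo
                dcols = dcols.reshape(n, cin, k, k, ho, wo)
                dxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        dxp[:, :, di : di + ho, dj : dj + wo] += dcols[:, :, di, dj]
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                a._accum(dxp)

        return Tensor._make(out, (a, w, b), backward)

    def conv_transpose2x2(self, weight: "Tensor", bias: "Tensor"):
        """Stride-2 2x2 transposed convolution (exact upsampling, no overlap).

        weight is (Cin, Cout, 2, 2); output spatial dims are doubled.
        """
        a, w, b = self, weight, bias
        x = a.data
        if x.ndim != 4 or x.shape[1] != w.shape[0]:
            raise DimensionError("conv_transpose2x2 shape mismatch")
        n, cin, h, wd = x.shape
        cout = w.shape[1]
        # out[n,o,2i+p,2j+q] = sum_c x[n,c,i,j] * w[c,o,p,q]
        t = np.tensordot(x, w.data, axes=([1], [0]))  # n,h,w,cout,2,2
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, cout, 2 * h, 2 * wd)
        out = out + b.data.reshape(1, cout, 1, 1)

        def backward(g):
            gt = g.reshape(n, cout, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.tensordot(x, gt, axes=([0, 2, 3], [0, 1, 2]))
                w._accum(gw)  # cin,cout,2,2
            if a.requires_grad:
                gx = np.tensordot(gt, w.data, axes=([3, 4, 5], [1, 2, 3]))
                a._accum(gx.transpose(0, 3, 1, 2))

        return Tensor._make(out, (a, w, b), backward)

    def maxpool2x2(self):
        """2x2 max pooling, stride 2; first-match tie-break."""
        a = self
        x = a.data
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise DimensionError("maxpool2x2 requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not a.requires_grad:
                return
            gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
            np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
            gr = gr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            a._accum(gr.reshape(n, c, h, w))

        return Tensor._make(out, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    parts = [Tensor._coerce(t) for t in tensors]
    sizes = [p.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accum(g[tuple(sl)])

    return Tensor._make(
        np.concatenate([p.data for p in parts], axis=axis), parts, backward
    )
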