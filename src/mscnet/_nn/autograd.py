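"""Minimal reverse-mode autodiff over numpy arrays.

Supports exactly the operations the segmentation networks need: broadcasted
elementwise arithmetic, reductions, shape surgery (reshape / transpose /
slicing / concatenation), 2-D convolution with channel groups, and 2x2 max
pooling.  Tensors wrap ``numpy.ndarray`` data; calling :meth:`Tensor.backward`
runs a topological sweep accumulating gradients into ``.grad``.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


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


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; recursion depth explodes on deep nets
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free graph references as we go
                node._backward = None
                node._parents = ()

    # -------------------------------------------------------------- factories
    @staticmethod
    def _from_op(data, parents, backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._from_op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g)

        return Tensor._from_op(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._from_op(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bw(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1))

        return Tensor._from_op(out_data, (a,), bw)

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._from_op(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._from_op(np.log(a.data), (a,), bw)

    def abs(self):
        a = self

        def bw(g):
            a._accumulate(g * np.sign(a.data))

        return Tensor._from_op(np.abs(a.data), (a,), bw)

    def relu(self):
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask)

        return Tensor._from_op(a.data * mask, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._from_op(out_data, (a,), bw)

    def clamp(self, lo: float, hi: float):
        """Clamp values; gradient passes through only where un-clamped."""
        a = self
        mask = (a.data >= lo) & (a.data <= hi)

        def bw(g):
            a._accumulate(g * mask)

        return Tensor._from_op(np.clip(a.data, lo, hi), (a,), bw)

    def matmul(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._from_op(a.data @ b.data, (a, b), bw)

    __matmul__ = matmul

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                g = np.expand_dims(g, tuple(ax % a.ndim for ax in axes))
            a._accumulate(np.broadcast_to(g, a.shape))

        return Tensor._from_op(out_data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ----------------------------------------------------------- shape surgery
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._from_op(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv))

        return Tensor._from_op(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, key):
        a = self

        parts = key if isinstance(key, tuple) else (key,)
        basic = all(isinstance(k, (int, slice, type(None), type(Ellipsis))) for k in parts)

        def bw(g):
            full = np.zeros_like(a.data)
            if basic:  # basic indexing never aliases, += is safe and fast
                full[key] += g
            else:
                np.add.at(full, key, g)
            a._accumulate(full)

        return Tensor._from_op(a.data[key], (a,), bw)

    def pad2d(self, pad: int):
        """Zero-pad the trailing two axes symmetrically by ``pad``."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]

        def bw(g):
            sl = tuple([slice(None)] * (a.ndim - 2) + [slice(pad, -pad)] * 2)
            a._accumulate(g[sl])

        return Tensor._from_op(np.pad(a.data, width), (a,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def cat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def softmax(x: Tensor, axis: int) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ------------------------------------------------------------------- conv ops
def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0,
           groups: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) on NCHW tensors.

    ``w`` has shape (C_out, C_in / groups, kh, kw).
    """
    n, cin, _, _ = x.shape
    cout, cin_g, kh, kw = w.shape
    if cin_g * groups != cin or cout % groups:
        raise ValueError(
            f"channel mismatch: input {cin}, weight {w.shape}, groups {groups}"
        )
    cout_g = cout // groups
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    hp, wp = xp.shape[2:]
    h, wd = hp - kh + 1, wp - kw + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,Cin,h,wd,kh,kw
    out = np.empty((n, cout, h, wd), dtype=x.data.dtype)
    for g in range(groups):
        cols = (
            win[:, g * cin_g:(g + 1) * cin_g]
            .transpose(0, 2, 3, 1, 4, 5)
            .reshape(n * h * wd, cin_g * kh * kw)
        )
        wg = w.data[g * cout_g:(g + 1) * cout_g].reshape(cout_g, -1)
        out[:, g * cout_g:(g + 1) * cout_g] = (
            (cols @ wg.T).reshape(n, h, wd, cout_g).transpose(0, 3, 1, 2)
        )
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(go):
        dxp = np.zeros_like(xp) if x.requires_grad else None
        for g in range(groups):
            gmat = (
                go[:, g * cout_g:(g + 1) * cout_g]
                .transpose(0, 2, 3, 1)
                .reshape(n * h * wd, cout_g)
            )
            wg = w.data[g * cout_g:(g + 1) * cout_g].reshape(cout_g, -1)
            if w.requires_grad:
                cols = (
                    win[:, g * cin_g:(g + 1) * cin_g]
                    .transpose(0, 2, 3, 1, 4, 5)
                    .reshape(n * h * wd, cin_g * kh * kw)
                )
                dwg = (gmat.T @ cols).reshape(cout_g, cin_g, kh, kw)
                if w.grad is None:
                    w.grad = np.zeros_like(w.data)
                w.grad[g * cout_g:(g + 1) * cout_g] += dwg
            if dxp is not None:
                dcols = (gmat @ wg).reshape(n, h, wd, cin_g, kh, kw)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, g * cin_g:(g + 1) * cin_g, i:i + h, j:j + wd] += (
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                        )
        if dxp is not None:
            x._accumulate(dxp[:, :, p:p + x.shape[2], p:p + x.shape[3]] if p else dxp)
        if b is not None and b.requires_grad:
            b._accumulate(go.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out, parents, bw)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    r = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out = r.max(axis=(3, 5))

    def bw(g):
        mask = r == out[:, :, :, None, :, None]
        cnt = mask.sum(axis=(3, 5), keepdims=True)
        dr = mask * (g[:, :, :, None, :, None] / cnt)
        x._accumulate(dr.reshape(n, c, h, w))

    return Tensor._from_op(out, (x,), bw)


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Factor-2 bilinear up-sampling of the trailing two axes.

    Uses half-pixel-centre alignment: output sample 2i mixes inputs i-1 and i
    with weights 1/4 and 3/4 (clamped at the borders), and symmetrically for
    2i+1.  Built from differentiable slicing so no bespoke backward is needed.
    """

    def up_last(t: Tensor) -> Tensor:
        left = cat([t[..., :1], t[..., :-1]], axis=-1)
        right = cat([t[..., 1:], t[..., -1:]], axis=-1)
        even = t * 0.75 + left * 0.25
        odd = t * 0.75 + right * 0.25
        stacked = cat(
            [even.reshape(*t.shape, 1), odd.reshape(*t.shape, 1)], axis=-1
        )
        return stacked.reshape(*t.shape[:-1], 2 * t.shape[-1])

    perm = tuple(range(x.ndim - 2)) + (x.ndim - 1, x.ndim - 2)
    x = up_last(x)                 # widen W
    x = up_last(x.transpose(perm)) # widen H
    return x.transpose(perm)
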