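"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run tape covering exactly the operations needed by the
3D segmentation networks in this package: 3D convolution (arbitrary
per-axis stride), non-overlapping transposed convolution, 2x2x2 max
pooling, batch/instance normalization, element-wise maximum (maxout
competition), channel/spatial pooling, dense layers, channel softmax and
weighted soft-Dice reduction.  Every operation's gradient is verified
against central finite differences in the test suite.

Arrays are laid out ``(N, C, X, Y, Z)``.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable tape construction (inference / metric evaluation)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; graphs are deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the tape as we go
            node._backward = None
            node._parents = ()


def _result(data, parents, backward):
    out = Tensor(data)
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise ops

def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _result(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Broadcasting multiply (used for channel / spatial gating)."""
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _result(data, (a, b), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise maximum: the maxout competition primitive."""
    mask = a.data >= b.data
    data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(np.where(mask, g, 0))
        if b.requires_grad:
            b._accum(np.where(mask, 0, g))

    return _result(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, 0)

    def backward(g):
        x._accum(np.where(mask, g, 0))

    return _result(data, (x,), backward)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        x._accum(np.where(mask, g, slope * g))

    return _result(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * data * (1.0 - data))

    return _result(data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _result(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution

def _triple(v):
    if np.isscalar(v):
        return (int(v),) * 3
    return tuple(int(x) for x in v)


def _im2col(xp: np.ndarray, k, stride):
    """(N,C,X,Y,Z) padded -> (N*vox_out, C*kx*ky*kz) patch matrix."""
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=(2, 3, 4))
    sx, sy, sz = stride
    win = win[:, :, ::sx, ::sy, ::sz]
    n, c, ox, oy, oz = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        n * ox * oy * oz, c * k[0] * k[1] * k[2]
    )
    return np.ascontiguousarray(cols), (ox, oy, oz)


def _raw_corr(x: np.ndarray, w: np.ndarray, padding, stride=(1, 1, 1)):
    """Plain cross-correlation used by forward and backward passes."""
    px, py, pz = padding
    xp = np.pad(x, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))
    k = w.shape[2:]
    cols, out_sp = _im2col(xp, k, stride)
    wm = w.reshape(w.shape[0], -1)
    out = cols @ wm.T
    n = x.shape[0]
    out = out.reshape(n, *out_sp, w.shape[0]).transpose(0, 4, 1, 2, 3)
    return np.ascontiguousarray(out), cols


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=1) -> Tensor:
    """3D cross-correlation; ``w`` is ``(Cout, Cin, kx, ky, kz)``."""
    stride = _triple(stride)
    padding = _triple(padding)
    k = w.data.shape[2:]
    data, cols = _raw_corr(x.data, w.data, padding, stride)
    if b is not None:
        data += b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        n, cout = g.shape[:2]
        gm = np.ascontiguousarray(
            g.transpose(0, 2, 3, 4, 1).reshape(-1, cout)
        )
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(w.data.shape))
        if x.requires_grad:
            # dx = correlation of (zero-dilated) g with the flipped kernel
            wf = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            if stride != (1, 1, 1):
                sx, sy, sz = stride
                gx, gy, gz = g.shape[2:]
                gd = np.zeros(
                    (n, cout, (gx - 1) * sx + 1, (gy - 1) * sy + 1,
                     (gz - 1) * sz + 1), dtype=g.dtype,
                )
                gd[:, :, ::sx, ::sy, ::sz] = g
            else:
                gd = g
            # full correlation, then crop the forward padding; windows may
            # not have covered the input tail, so zero-pad any shortfall
            bp = tuple(kk - 1 for kk in k)
            dx, _ = _raw_corr(gd, np.ascontiguousarray(wf), bp)
            target = x.data.shape[2:]
            pad = [(0, 0), (0, 0)]
            for have, want, pp in zip(dx.shape[2:], target, padding):
                pad.append((0, max(0, want + pp - have)))
            if any(q != (0, 0) for q in pad[2:]):
                dx = np.pad(dx, pad)
            sl = tuple(slice(pp, pp + t) for pp, t in zip(padding, target))
            x._accum(dx[(slice(None), slice(None)) + sl])

    return _result(data, parents, backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, factor=2) -> Tensor:
    """Transposed convolution with kernel == stride (non-overlapping).

    ``w`` is ``(Cin, Cout, fx, fy, fz)``; each input voxel expands into an
    ``fx*fy*fz`` output block, upsampling by the per-axis factor.
    """
    f = _triple(factor)
    n, cin, X, Y, Z = x.data.shape
    cout = w.data.shape[1]
    t = np.tensordot(x.data, w.data, axes=([1], [0]))
    # (N, X, Y, Z, Cout, fx, fy, fz) -> (N, Cout, X, fx, Y, fy, Z, fz)
    t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)
    data = np.ascontiguousarray(t).reshape(n, cout, X * f[0], Y * f[1], Z * f[2])
    if b is not None:
        data = data + b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        blocks = g.reshape(n, cout, X, f[0], Y, f[1], Z, f[2])
        blocks = blocks.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # N,X,Y,Z,Cout,fx,fy,fz
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            dw = np.tensordot(x.data, blocks, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
            w._accum(dw)
        if x.requires_grad:
            dx = np.tensordot(blocks, w.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
            x._accum(np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3)))

    return _result(data, parents, backward)


def maxpool3d(x: Tensor, factor=2) -> Tensor:
    """Max pooling with non-overlapping per-axis windows."""
    f = _triple(factor)
    n, c, X, Y, Z = x.data.shape
    if X % f[0] or Y % f[1] or Z % f[2]:
        raise ValueError(f"spatial shape {(X, Y, Z)} not divisible by pool {f}")
    r = x.data.reshape(n, c, X // f[0], f[0], Y // f[1], f[1], Z // f[2], f[2])
    r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, X // f[0], Y // f[1], Z // f[2], f[0] * f[1] * f[2]
    )
    idx = r.argmax(axis=-1)
    data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gr = np.zeros_like(r)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gr = gr.reshape(n, c, X // f[0], Y // f[1], Z // f[2], f[0], f[1], f[2])
        gr = gr.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, X, Y, Z)
        x._accum(gr)

    return _result(data, (x,), backward)


# ---------------------------------------------------------------------------
# normalization

def normalize(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
              eps: float = 1e-5, mean=None, var=None) -> Tensor:
    """Affine normalization over ``axes``.

    With ``mean``/``var`` given (inference), uses those fixed statistics;
    otherwise computes them from the batch. ``gamma``/``beta`` are shaped
    to broadcast, e.g. ``(1, C, 1, 1, 1)``.
    """
    fixed = mean is not None
    if not fixed:
        mean = x.data.mean(axis=axes, keepdims=True)
        var = x.data.var(axis=axes, keepdims=True)
    iv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean) * iv
    data = gamma.data * xhat + beta.data

    def backward(g):
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if x.requires_grad:
            dxhat = g * gamma.data
            if fixed:
                x._accum(dxhat * iv)
            else:
                m = np.prod([x.data.shape[a] for a in axes])
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                x._accum(iv * (dxhat - s1 / m - xhat * s2 / m))

    return _result(data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pooling / dense / attention helpers

def global_pool(x: Tensor, kind: str) -> Tensor:
    """Spatial pooling (N,C,X,Y,Z) -> (N,C); kind in {mean, max}."""
    n, c = x.data.shape[:2]
    flat = x.data.reshape(n, c, -1)
    if kind == "mean":
        data = flat.mean(axis=-1)

        def backward(g):
            gg = np.broadcast_to(
                g[:, :, None] / flat.shape[-1], flat.shape
            ).reshape(x.data.shape)
            x._accum(gg.copy())
    elif kind == "max":
        idx = flat.argmax(axis=-1)
        data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gf = np.zeros_like(flat)
            np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
            x._accum(gf.reshape(x.data.shape))
    else:  # pragma: no cover
        raise ValueError(kind)
    return _result(data, (x,), backward)


def channel_pool(x: Tensor, kind: str) -> Tensor:
    """Pool over the channel axis, keepdims: (N,C,X,Y,Z) -> (N,1,X,Y,Z)."""
    if kind == "mean":
        data = x.data.mean(axis=1, keepdims=True)

        def backward(g):
            x._accum(np.broadcast_to(g / x.data.shape[1], x.data.shape).copy())
    elif kind == "max":
        idx = x.data.argmax(axis=1, keepdims=True)
        data = np.take_along_axis(x.data, idx, axis=1)

        def backward(g):
            gx = np.zeros_like(x.data)
            np.put_along_axis(gx, idx, g, axis=1)
            x._accum(gx)
    else:  # pragma: no cover
        raise ValueError(kind)
    return _result(data, (x,), backward)


def linear(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Dense layer: (N, Cin) @ (Cout, Cin)^T + b."""
    data = x.data @ w.data.T
    if b is not None:
        data = data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=0))
        if w.requires_grad:
            w._accum(g.T @ x.data)
        if x.requires_grad:
            x._accum(g @ w.data)

    return _result(data, parents, backward)


def reshape(x: Tensor, shape) -> Tensor:
    data = x.data.reshape(shape)

    def backward(g):
        x._accum(g.reshape(x.data.shape))

    return _result(data, (x,), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (the class axis)."""
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accum(p * (g - dot))

    return _result(p, (x,), backward)


def weighted_soft_dice_loss(probs: Tensor, ref_onehot: np.ndarray,
                            class_weights: np.ndarray,
                            voxel_weights: np.ndarray | float = 1.0,
                            eps: float = 1e-5) -> Tensor:
    """1 - sum_l w_l * D_l with D_l the voxel-weighted soft Dice.

    ``probs`` is (N, C, X, Y, Z); ``ref_onehot`` broadcasts to it;
    ``voxel_weights`` broadcasts over the class axis. Sums pool the batch.
    """
    p = probs.data
    m = np.asarray(voxel_weights, dtype=p.dtype)
    r = ref_onehot.astype(p.dtype, copy=False)
    if p.ndim == 5:
        axes, caxis = (0, 2, 3, 4), 1
    elif p.ndim == 4:  # single volume (C, X, Y, Z)
        axes, caxis = (1, 2, 3), 0
    else:
        raise ValueError("probs must be (N,C,X,Y,Z) or (C,X,Y,Z)")
    mp = m * p
    num = (mp * r).sum(axis=axes)            # per-class A_l
    den = mp.sum(axis=axes) + (m * r).sum(axis=axes)
    w = np.asarray(class_weights, dtype=p.dtype)
    dice = (2.0 * num + eps) / (den + eps)
    loss = 1.0 - float((w * dice).sum())

    def backward(g):
        gs = float(g)
        shape = [1] * p.ndim
        shape[caxis] = p.shape[caxis]
        num_b = num.reshape(shape)
        den_b = den.reshape(shape)
        w_b = w.reshape(shape)
        ddice_dp = m * (2.0 * r * (den_b + eps) - (2.0 * num_b + eps)) / (
            den_b + eps
        ) ** 2
        probs._accum(-gs * w_b * ddice_dp)

    return _result(np.asarray(loss), (probs,), backward)
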