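"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's networks are small enough (desk-scale 2-D segmentation) that a
tape-based engine over float64 ndarrays is both fast enough on one CPU core
and bit-for-bit reproducible, which the training pipeline relies on.  The op
set is exactly what the segmentation blocks need: broadcasting arithmetic,
batched matmul, softmax, GELU, channel/group normalisation, stride-1 "same"
convolutions (dense and depthwise), 2x2 max pooling, 2x bilinear upsampling
and the 2x2 interleave/deinterleave pair used by the Haar transform.

Gradients accumulate into ``Tensor.grad`` (a plain ndarray) after calling
``backward()`` on a scalar result.  Graph recording can be suspended with the
``no_grad`` context manager for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "softmax",
    "gelu",
    "conv2d",
    "depthwise_conv2d",
    "maxpool2x2",
    "upsample_bilinear2x",
    "interleave2x2",
    "pad_bottom_right",
    "layer_norm_channels",
    "group_norm",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Suspend graph recording (inference / metric evaluation)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an attached gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

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

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: training graphs exceed recursion limits
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
        self.accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self.accumulate(-g)

        return Tensor(-self.data, self.requires_grad, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(out_data, self.requires_grad or other.requires_grad, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other.accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor(out_data, self.requires_grad or other.requires_grad, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data**exponent

        def bw(g):
            self.accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self.accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape)
                )
            if other.requires_grad:
                other.accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape)
                )

        return Tensor(out_data, self.requires_grad or other.requires_grad, (self, other), bw)

    # -- shaping ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        src_shape = self.data.shape

        def bw(g):
            self.accumulate(g.reshape(src_shape))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bw(g):
            self.accumulate(g.transpose(inv))

        return Tensor(self.data.transpose(axes), self.requires_grad, (self,), bw)

    def __getitem__(self, idx):
        out_data = self.data[idx]
        src_shape = self.data.shape

        def bw(g):
            full = np.zeros(src_shape)
            full[idx] += g  # basic (non-fancy) indexing only
            self.accumulate(full)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    # -- reductions & elementwise ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        src_shape = self.data.shape

        def bw(g):
            if axis is None:
                self.accumulate(np.broadcast_to(g, src_shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self.accumulate(np.broadcast_to(g, src_shape).copy())

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self.accumulate(g * out_data)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def log(self):
        def bw(g):
            self.accumulate(g / self.data)

        return Tensor(np.log(self.data), self.requires_grad, (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self.accumulate(g * 0.5 / out_data)

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic

        def bw(g):
            self.accumulate(g * out_data * (1.0 - out_data))

        return Tensor(out_data, self.requires_grad, (self,), bw)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self.accumulate(g * mask)

        return Tensor(out_data, self.requires_grad, (self,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    req = any(t.requires_grad for t in tensors)
    return Tensor(out_data, req, tensors, bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    y = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        x.accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    return Tensor(y, x.requires_grad, (x,), bw)


_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    phi = 0.5 * (1.0 + erf(x.data * _INV_SQRT2))
    out_data = x.data * phi

    def bw(g):
        pdf = np.exp(-0.5 * x.data**2) * _INV_SQRT2PI
        x.accumulate(g * (phi + x.data * pdf))

    return Tensor(out_data, x.requires_grad, (x,), bw)


# ---------------------------------------------------------------------------
# convolutions (stride 1, odd kernels, "same" zero padding)
# ---------------------------------------------------------------------------


def _conv_same_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Cross-correlate (B,C,H,W) with (O,C,kh,kw), stride 1, same padding."""
    B, C, H, W = x.shape
    O, _, kh, kw = w.shape
    if kh == 1 and kw == 1:
        return np.einsum("oc,bchw->bohw", w[:, :, 0, 0], x, optimize=True)
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    sw = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # (B,C,H,W,kh,kw)
    cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(B * H * W, C * kh * kw)
    out = cols @ w.reshape(O, -1).T
    return out.reshape(B, H, W, O).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Dense 2-D convolution, stride 1, zero "same" padding, odd kernel."""
    x, w = as_tensor(x), as_tensor(w)
    O, C, kh, kw = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes for symmetric same-padding")
    if x.data.shape[1] != C:
        raise ValueError(f"conv2d channel mismatch: input {x.data.shape[1]} vs kernel {C}")
    out_data = _conv_same_raw(x.data, w.data)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            B, _, H, W = x.data.shape
            if kh == 1 and kw == 1:
                gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))  # (O,C)
                w.accumulate(gw.reshape(O, C, 1, 1))
            else:
                xp = np.pad(x.data, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
                gw = np.empty_like(w.data)
                for i in range(kh):
                    for j in range(kw):
                        gw[:, :, i, j] = np.tensordot(
                            g, xp[:, :, i:i + H, j:j + W], axes=([0, 2, 3], [0, 2, 3])
                        )
                w.accumulate(gw)
        if x.requires_grad:
            w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,O,kh,kw)
            x.accumulate(_conv_same_raw(g, np.ascontiguousarray(w_flip)))

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(out_data, req, parents, bw)


def _dwconv_same_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Depthwise cross-correlation of (B,C,H,W) with (C,kh,kw).

    Computed as a shift-and-accumulate over the k*k taps, which beats an
    im2col contraction for the small per-channel kernels used here.
    """
    C, kh, kw = w.shape
    B, _, H, W = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
    out = np.zeros((B, C, H, W), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            out += w[:, i, j].reshape(1, C, 1, 1) * xp[:, :, i:i + H, j:j + W]
    return out


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Depthwise conv: one (kh,kw) kernel per channel, no cross-channel mixing."""
    x, w = as_tensor(x), as_tensor(w)
    C, kh, kw = w.data.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("depthwise_conv2d requires odd kernel sizes")
    if x.data.shape[1] != C:
        raise ValueError(
            f"depthwise_conv2d channel mismatch: input {x.data.shape[1]} vs kernel {C}"
        )
    out_data = _dwconv_same_raw(x.data, w.data)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, C, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            B, _, H, W = x.data.shape
            xp = np.pad(x.data, ((0, 0), (0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2)))
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, i, j] = np.einsum(
                        "bchw,bchw->c", g, xp[:, :, i:i + H, j:j + W]
                    )
            w.accumulate(gw)
        if x.requires_grad:
            x.accumulate(_dwconv_same_raw(g, np.ascontiguousarray(w.data[:, ::-1, ::-1])))

    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    return Tensor(out_data, req, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 requires even spatial size, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gf = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x.accumulate(gx.reshape(B, C, H, W))

    return Tensor(out_data, x.requires_grad, (x,), bw)


def _up2_along(x: np.ndarray, axis: int) -> np.ndarray:
    """Double one spatial axis with align_corners=False bilinear weights.

    out[2i] = 0.25*x[i-1] + 0.75*x[i] and out[2i+1] = 0.75*x[i] + 0.25*x[i+1]
    with edge clamping; separable application gives full 2-D upsampling.
    """
    x = np.moveaxis(x, axis, -1)
    prev = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    nxt = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x + 0.25 * prev
    out[..., 1::2] = 0.75 * x + 0.25 * nxt
    return np.moveaxis(out, -1, axis)


def _down2_along(g: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_up2_along` (scatters gradient back)."""
    g = np.moveaxis(g, axis, -1)
    ge = g[..., 0::2]
    go = g[..., 1::2]
    gx = 0.75 * (ge + go)
    # from even outputs: gx[i-1] += 0.25*ge[i]  (ge[0] clamps onto gx[0])
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    # from odd outputs: gx[i+1] += 0.25*go[i]  (go[-1] clamps onto gx[-1])
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(gx, -1, axis)


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Double both spatial axes of (B,C,H,W) by separable bilinear interpolation."""
    x = as_tensor(x)
    out_data = _up2_along(_up2_along(x.data, 2), 3)

    def bw(g):
        x.accumulate(_down2_along(_down2_along(g, 3), 2))

    return Tensor(out_data, x.requires_grad, (x,), bw)


def interleave2x2(a: Tensor, b: Tensor, c: Tensor, d: Tensor) -> Tensor:
    """Assemble (B,C,2H,2W) from four (B,C,H,W) quarter-phase maps.

    a fills even rows/even cols, b even rows/odd cols, c odd/even, d odd/odd —
    the synthesis layout of a single-level 2-D polyphase transform.
    """
    a, b, c, d = map(as_tensor, (a, b, c, d))
    B, C, H, W = a.data.shape
    out_data = np.empty((B, C, 2 * H, 2 * W))
    out_data[:, :, 0::2, 0::2] = a.data
    out_data[:, :, 0::2, 1::2] = b.data
    out_data[:, :, 1::2, 0::2] = c.data
    out_data[:, :, 1::2, 1::2] = d.data

    def bw(g):
        for t, (si, sj) in zip((a, b, c, d), ((0, 0), (0, 1), (1, 0), (1, 1))):
            if t.requires_grad:
                t.accumulate(g[:, :, si::2, sj::2])

    req = any(t.requires_grad for t in (a, b, c, d))
    return Tensor(out_data, req, (a, b, c, d), bw)


def pad_bottom_right(x: Tensor, ph: int, pw: int, mode: str = "reflect") -> Tensor:
    """Pad by one row/column at bottom/right (reflect, or edge for size-1 axes)."""
    x = as_tensor(x)
    if ph not in (0, 1) or pw not in (0, 1):
        raise ValueError("pad_bottom_right supports padding of 0 or 1 only")
    B, C, H, W = x.data.shape
    hmode = mode if (H > 1 or ph == 0) else "edge"
    wmode = mode if (W > 1 or pw == 0) else "edge"
    out = np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, 0)), mode=hmode)
    out = np.pad(out, ((0, 0), (0, 0), (0, 0), (0, pw)), mode=wmode)
    h_src = (H - 2 if H > 1 else 0) if mode == "reflect" else H - 1
    w_src = (W - 2 if W > 1 else 0) if mode == "reflect" else W - 1

    def bw(g):
        g = g.copy()
        if ph:
            g[:, :, h_src if H > 1 else 0, :] += g[:, :, H, :]
            g = g[:, :, :H, :]
        if pw:
            g[:, :, :, w_src if W > 1 else 0] += g[:, :, :, W]
            g = g[:, :, :, :W]
        x.accumulate(g)

    return Tensor(out, x.requires_grad, (x,), bw)


def layer_norm_channels(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the channel axis, independently per position."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    C = x.data.shape[1]
    mu = x.data.mean(axis=1, keepdims=True)
    var = x.data.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gm = gamma.data.reshape(1, C, 1, 1)
    out_data = gm * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = g * gm
            x.accumulate(
                inv_std
                * (
                    dxhat
                    - dxhat.mean(axis=1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
                )
            )

    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    return Tensor(out_data, req, (x, gamma, beta), bw)


def group_norm(
    x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-6
) -> Tensor:
    """Group normalisation over (channels-per-group, H, W), batch independent."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    B, C, H, W = x.data.shape
    if C % groups:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    xg = x.data.reshape(B, groups, C // groups, H, W)
    axes = (2, 3, 4)
    mu = xg.mean(axis=axes, keepdims=True)
    var = xg.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv_std
    xhat_full = xhat.reshape(B, C, H, W)
    gm = gamma.data.reshape(1, C, 1, 1)
    out_data = gm * xhat_full + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma.accumulate((g * xhat_full).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gm).reshape(B, groups, C // groups, H, W)
            gx = inv_std * (
                dxhat
                - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True)
            )
            x.accumulate(gx.reshape(B, C, H, W))

    req = x.requires_grad or gamma.requires_grad or beta.requires_grad
    return Tensor(out_data, req, (x, gamma, beta), bw)
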