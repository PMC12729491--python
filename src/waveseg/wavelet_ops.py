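"""Single-level 2-D Haar transforms on feature maps, and the wavelet-domain
convolution block built on them.

The transform uses the orthonormal Haar convention: each non-overlapping
2x2 block [[a, b], [c, d]] of a (B, C, H, W) map produces

    ll = (a + b + c + d) / 2      (low-frequency approximation)
    lh = (a - b + c - d) / 2      (horizontal detail: differences along width)
    hl = (a + b - c - d) / 2      (vertical detail: differences along height)
    hh = (a - b - c + d) / 2      (diagonal detail)

With the 1/2 normalisation the analysis matrix is orthonormal, so the
transform conserves energy (Parseval) and the synthesis transform is its
exact inverse.  Odd spatial sizes are reflect-padded by one row/column
before analysis and cropped back after synthesis.

The wavelet convolution block (``WtConv``) decomposes a feature map,
filters each of the four sub-bands with an independent depthwise
convolution, reconstructs with the inverse transform, and applies one final
depthwise convolution — letting the network treat low-frequency contour
content and directional high-frequency detail with separate learned filters.
Because the transform halves resolution, the sub-band convolutions also
double the block's effective receptive field at no extra cost.

All operations are differentiable through :mod:`waveseg.autograd`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .errors import ConfigurationError, ValidationError
from .nn import DepthwiseConv2d, Module

__all__ = [
    "ORTHONORMAL_HAAR",
    "WaveletSubbands",
    "haar_dwt2d",
    "haar_iwt2d",
    "WtConv",
    "wtconv_forward",
]

ORTHONORMAL_HAAR = "haar-orthonormal"


def _check_finite(arr: np.ndarray, op: str) -> None:
    if not np.isfinite(arr).all():
        bad = np.argwhere(~np.isfinite(arr))[0]
        axes = ("batch", "channel", "height", "width")
        where = ", ".join(f"{a}={i}" for a, i in zip(axes, bad))
        raise ValidationError(f"{op}: non-finite value at ({where})")


@dataclass
class WaveletSubbands:
    """The four half-resolution sub-bands of a single-level 2-D transform.

    ``original_size`` records the pre-padding (H, W) of the analysed map so
    that synthesis can crop back; it is ``None`` for hand-built quadruples.
    """

    ll: Tensor
    lh: Tensor
    hl: Tensor
    hh: Tensor
    convention_tag: str = ORTHONORMAL_HAAR
    original_size: tuple[int, int] | None = field(default=None)

    def __post_init__(self):
        self.ll, self.lh, self.hl, self.hh = map(
            as_tensor, (self.ll, self.lh, self.hl, self.hh)
        )
        shapes = {t.shape for t in (self.ll, self.lh, self.hl, self.hh)}
        if len(shapes) != 1:
            raise ValidationError(f"sub-band shapes differ: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.ll.shape

    def energy(self) -> float:
        """Total squared-sum energy over the four members."""
        return float(
            sum((t.data**2).sum() for t in (self.ll, self.lh, self.hl, self.hh))
        )


def haar_dwt2d(x: Tensor | np.ndarray) -> WaveletSubbands:
    """Single-level orthonormal Haar analysis of a (B, C, H, W) feature map.

    Odd H or W is reflect-padded by one row/column first; the returned
    sub-bands have spatial size (ceil(H/2), ceil(W/2)).
    """
    x = as_tensor(x)
    if x.ndim != 4:
        raise ValidationError(f"haar_dwt2d expects a 4-axis map, got shape {x.shape}")
    _check_finite(x.data, "haar_dwt2d")
    B, C, H, W = x.shape
    xp = x
    if H % 2 or W % 2:
        xp = ag.pad_bottom_right(x, H % 2, W % 2, mode="reflect")
    a = xp[:, :, 0::2, 0::2]
    b = xp[:, :, 0::2, 1::2]
    c = xp[:, :, 1::2, 0::2]
    d = xp[:, :, 1::2, 1::2]
    ll = (a + b + c + d) * 0.5
    lh = (a - b + c - d) * 0.5
    hl = (a + b - c - d) * 0.5
    hh = (a - b - c + d) * 0.5
    return WaveletSubbands(ll, lh, hl, hh, ORTHONORMAL_HAAR, (H, W))


def haar_iwt2d(s: WaveletSubbands) -> Tensor:
    """Synthesis transform: exact inverse of :func:`haar_dwt2d`.

    If the analysis padded an odd-sized input, the reconstruction is cropped
    back to ``s.original_size``.
    """
    ll, lh, hl, hh = s.ll, s.lh, s.hl, s.hh
    a = (ll + lh + hl + hh) * 0.5
    b = (ll - lh + hl - hh) * 0.5
    c = (ll + lh - hl - hh) * 0.5
    d = (ll - lh - hl + hh) * 0.5
    y = ag.interleave2x2(a, b, c, d)
    if s.original_size is not None:
        H, W = s.original_size
        if (H, W) != y.shape[2:]:
            y = y[:, :, :H, :W]
    return y


class WtConv(Module):
    """Wavelet-domain convolution block.

    Pipeline: DWT -> independent depthwise conv per sub-band ("same"
    padding) -> IWT over the processed quadruple -> final depthwise conv.
    Output shape equals input shape.  All five depthwise stacks hold
    independent weights; biases start at zero.
    """

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        if kernel_size % 2 == 0:
            raise ConfigurationError("wavelet block kernels must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        self.conv_ll = DepthwiseConv2d(channels, kernel_size, rng)
        self.conv_lh = DepthwiseConv2d(channels, kernel_size, rng)
        self.conv_hl = DepthwiseConv2d(channels, kernel_size, rng)
        self.conv_hh = DepthwiseConv2d(channels, kernel_size, rng)
        self.conv_final = DepthwiseConv2d(channels, kernel_size, rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"wavelet block configured for {self.channels} channels, input has {x.shape[1]}"
            )
        s = haar_dwt2d(x)
        processed = WaveletSubbands(
            self.conv_ll(s.ll),
            self.conv_lh(s.lh),
            self.conv_hl(s.hl),
            self.conv_hh(s.hh),
            s.convention_tag,
            s.original_size,
        )
        y_rec = haar_iwt2d(processed)
        return self.conv_final(y_rec)

    def set_identity(self) -> None:
        """Configure every depthwise stack as a centred delta (block becomes a no-op)."""
        for conv in (self.conv_ll, self.conv_lh, self.conv_hl, self.conv_hh, self.conv_final):
            conv.set_identity()

    def set_zero(self) -> None:
        for conv in (self.conv_ll, self.conv_lh, self.conv_hl, self.conv_hh, self.conv_final):
            conv.weight.data[:] = 0.0
            if conv.bias is not None:
                conv.bias.data[:] = 0.0


def wtconv_forward(x: Tensor | np.ndarray, block: WtConv) -> Tensor:
    """Functional entry point for the wavelet convolution block."""
    return block(x)
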