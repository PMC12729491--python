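"""Weighted contextual fusion (WCF) of two same-shape feature streams.

One stream (x1, in the network: the encoder skip feature) generates channel
attention weights; the other (x2, the upsampled decoder feature) is
transformed and modulated by them:

    W_attn = softmax_channels( Linear(x1) )           # per-position simplex
    F_in   = Linear( DWConv(x2) )                     # spatial + channel transform
    y      = DWConv( W_attn * F_in )                  # final integration

The softmax runs over the channel axis independently at every spatial
position, so the weights form a spatially varying distribution over
channels: at each pixel the encoder stream decides which decoder channels
to amplify or suppress.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .errors import ConfigurationError, FusionShapeError
from .nn import Conv2d, DepthwiseConv2d, Module

__all__ = ["WCF"]


class WCF(Module):
    """Fusion block; both linear maps are square (C -> C), both depthwise
    stacks carry one odd-sized kernel per channel (default 3x3)."""

    def __init__(self, channels: int, kernel_size: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels = channels
        # channel-wise linear maps realised as 1x1 convolutions
        self.weight_linear = Conv2d(channels, channels, 1, rng)
        self.pre_dwconv = DepthwiseConv2d(channels, kernel_size, rng)
        self.transform_linear = Conv2d(channels, channels, 1, rng)
        self.post_dwconv = DepthwiseConv2d(channels, kernel_size, rng)

    def _check_channels(self, x: Tensor, name: str) -> None:
        if x.shape[1] != self.channels:
            raise ConfigurationError(
                f"fusion block configured for {self.channels} channels, "
                f"{name} has {x.shape[1]}"
            )

    def weights(self, x1: Tensor | np.ndarray) -> Tensor:
        """Per-position channel attention weights (softmax over channels)."""
        x1 = as_tensor(x1)
        self._check_channels(x1, "x1")
        logits = self.weight_linear(x1)
        return ag.softmax(logits, axis=1)

    def transform(self, x2: Tensor | np.ndarray) -> Tensor:
        """Features to be weighted: channel linear after depthwise conv."""
        x2 = as_tensor(x2)
        self._check_channels(x2, "x2")
        return self.transform_linear(self.pre_dwconv(x2))

    def forward(self, x1: Tensor | np.ndarray, x2: Tensor | np.ndarray) -> Tensor:
        x1, x2 = as_tensor(x1), as_tensor(x2)
        if x1.shape != x2.shape:
            raise FusionShapeError(
                f"fusion streams disagree in shape: x1 {x1.shape} vs x2 {x2.shape} "
                "(upsample the decoder stream before fusing)"
            )
        self._check_channels(x1, "x1")
        w_attn = self.weights(x1)
        f_in = self.transform(x2)
        return self.post_dwconv(w_attn * f_in)
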