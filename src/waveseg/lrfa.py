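"""Large receptive field attention (LRFA) block.

Combines convolutional local feature extraction with exact multi-head
self-attention over spatial positions:

1. preprocess:  Conv3x3( GELU( Conv1x1( LN(x) ) ) ), where LN normalises the
   channel vector at each spatial position,
2. aggregate:   sum of three parallel depthwise convolutions with distinct
   odd kernel sizes (default 3/5/7), giving a multi-scale receptive field,
3. attention:   spatial positions become tokens with channel-dim embeddings;
   standard scaled-dot-product multi-head self-attention (learned Q/K/V and
   output projections, no positional encoding),
4. output:      residual  y = x + Conv1x1(attention output).

Exact attention is quadratic in the token count, so the block enforces a
token budget (H*W <= max_tokens) and is meant for deep, low-resolution
stages of an encoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .errors import CapacityError, ConfigurationError
from .nn import Conv2d, DepthwiseConv2d, LayerNorm2d, Linear, Module

__all__ = ["LRFAConfig", "LRFAState", "LRFA"]


@dataclass(frozen=True)
class LRFAConfig:
    channels: int
    branch_kernel_sizes: tuple[int, int, int] = (3, 5, 7)
    num_heads: int = 4
    max_tokens: int = 1024

    def __post_init__(self):
        if self.channels <= 0:
            raise ConfigurationError("channels must be positive")
        if self.channels % self.num_heads:
            raise ConfigurationError(
                f"channels ({self.channels}) must be divisible by num_heads ({self.num_heads})"
            )
        ks = self.branch_kernel_sizes
        if len(ks) != 3 or len(set(ks)) != 3 or any(k % 2 == 0 for k in ks):
            raise ConfigurationError("branch kernel sizes must be three distinct odd integers")
        if self.max_tokens <= 0:
            raise ConfigurationError("max_tokens must be positive")


@dataclass
class LRFAState:
    """Intermediate maps retained when introspection is requested."""

    x_local: Tensor
    x_agg: Tensor
    x_attn: Tensor


class LRFA(Module):
    def __init__(self, config: LRFAConfig, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        C = config.channels
        self.config = config
        self.norm = LayerNorm2d(C)
        self.conv1x1 = Conv2d(C, C, 1, rng)
        self.conv3x3 = Conv2d(C, C, 3, rng)
        self.branches = [DepthwiseConv2d(C, k, rng) for k in config.branch_kernel_sizes]
        self.branch_a, self.branch_b, self.branch_c = self.branches
        self.q_proj = Linear(C, C, rng)
        self.k_proj = Linear(C, C, rng)
        self.v_proj = Linear(C, C, rng)
        self.out_proj = Linear(C, C, rng)
        self.final_proj = Conv2d(C, C, 1, rng)

    # -- stages -----------------------------------------------------------
    def preprocess(self, x: Tensor | np.ndarray) -> Tensor:
        x = as_tensor(x)
        if x.shape[1] != self.config.channels:
            raise ConfigurationError(
                f"LRFA configured for {self.config.channels} channels, input has {x.shape[1]}"
            )
        return self.conv3x3(ag.gelu(self.conv1x1(self.norm(x))))

    def aggregate(self, x_local: Tensor | np.ndarray) -> Tensor:
        x_local = as_tensor(x_local)
        out = self.branch_a(x_local)
        out = out + self.branch_b(x_local)
        out = out + self.branch_c(x_local)
        return out

    def attention(self, x_agg: Tensor | np.ndarray, return_weights: bool = False):
        x_agg = as_tensor(x_agg)
        B, C, H, W = x_agg.shape
        T = H * W
        if T > self.config.max_tokens:
            raise CapacityError(
                f"{T} spatial tokens exceed the exact-attention budget of "
                f"{self.config.max_tokens}; place this block at a deeper (lower-resolution) stage"
            )
        h = self.config.num_heads
        dh = C // h
        tokens = x_agg.reshape(B, C, T).transpose(0, 2, 1)  # (B, T, C)
        q = self.q_proj(tokens).reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        k = self.k_proj(tokens).reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        v = self.v_proj(tokens).reshape(B, T, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = ag.softmax(scores, axis=-1)  # (B, h, T, T); each row a distribution
        mixed = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, C)
        out = self.out_proj(mixed).transpose(0, 2, 1).reshape(B, C, H, W)
        if return_weights:
            return out, attn
        return out

    def forward(self, x: Tensor | np.ndarray, return_state: bool = False):
        x = as_tensor(x)
        x_local = self.preprocess(x)
        x_agg = self.aggregate(x_local)
        x_attn = self.attention(x_agg)
        y = x + self.final_proj(x_attn)
        if return_state:
            return y, LRFAState(x_local, x_agg, x_attn)
        return y
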