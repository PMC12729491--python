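"""Neural-network layers on top of :mod:`waveseg.autograd`.

Initialisation is fully deterministic: every layer draws its weights from the
``numpy.random.Generator`` passed to its constructor, and modules create
sub-modules in a fixed order, so a single seeded generator reproduces a model
bit-for-bit.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Conv2d",
    "DepthwiseConv2d",
    "Linear",
    "LayerNorm2d",
    "GroupNorm2d",
    "Sequential",
    "GELU",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter traversal and state (de)serialisation."""

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(full + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        self._items = list(modules)

    def append(self, m: Module) -> None:
        self._items.append(m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._items):
            yield from m.named_parameters(f"{prefix}{i}.")


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    """Dense conv, stride 1, same padding, odd kernel; Kaiming-uniform init, zero bias."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming_uniform(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    """One odd-sized kernel per channel (no cross-channel mixing)."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 bias: bool = True):
        fan_in = kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming_uniform(rng, (channels, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(channels)) if bias else None
        self.channels = channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias)

    def set_identity(self) -> None:
        """Make this layer a no-op (centred delta kernel, zero bias)."""
        k = self.kernel_size
        self.weight.data[:] = 0.0
        self.weight.data[:, k // 2, k // 2] = 1.0
        if self.bias is not None:
            self.bias.data[:] = 0.0


class Linear(Module):
    """Affine map on the last axis of a (..., in_features) tensor."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Parameter(_kaiming_uniform(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm2d(Module):
    """Channel-axis layer norm at each spatial position of a (B,C,H,W) map."""

    def __init__(self, channels: int, eps: float = 1e-6):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm_channels(x, self.gamma, self.beta, self.eps)


class GroupNorm2d(Module):
    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-6):
        if channels % groups:
            groups = 1  # fall back to layer-wide norm for indivisible widths
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.groups = groups
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.group_norm(x, self.gamma, self.beta, self.groups, self.eps)


class GELU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.gelu(x)


class Sequential(Module):
    def __init__(self, *modules: Module):
        self._items = ModuleList(modules)

    def forward(self, x: Tensor) -> Tensor:
        for m in self._items:
            x = m(x)
        return x

    def named_parameters(self, prefix: str = ""):
        yield from self._items.named_parameters(prefix)
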