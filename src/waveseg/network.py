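"""U-shaped encoder-decoder assembly with wavelet, attention and fusion blocks.

The backbone is a classic U-Net: ``num_stages`` encoder stages whose channel
widths double from ``base_width``, 2x max-pool downsampling between stages, a
mirrored decoder with 2x upsampling, and a 1x1 head squashed to (0,1).
Each stage block is two 3x3 conv + group-norm + GELU units (group norm keeps
desk-scale CPU training with small batches stable).

Three refinement blocks are placed by configuration:

* ``WtConv`` (wavelet-domain depthwise filtering) appended inside the
  encoder stages listed in ``wtconv_stages`` — deep stages by default,
  where frequency-separated filtering of contour vs. detail pays off;
* ``LRFA`` (multi-scale depthwise aggregation + exact multi-head
  self-attention) appended inside ``lrfa_stages`` — the bottleneck by
  default, where the token count permits exact attention;
* ``WCF`` replaces plain skip concatenation at every skip junction when
  ``use_wcf`` is set: the encoder skip stream generates per-position channel
  attention weights that modulate the upsampled decoder stream.

The ablation factory enumerates the eight standard variants (baseline, each
block alone, each block removed from the full model, full model) under a
shared seed so controlled comparisons stay controlled.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor
from .errors import ConfigurationError, ValidationError
from .lrfa import LRFA, LRFAConfig
from .nn import GELU, Conv2d, GroupNorm2d, Module, ModuleList, Sequential
from .wavelet_ops import WtConv
from .wcf import WCF

__all__ = [
    "ModelConfig",
    "AblationVariant",
    "SegmentationUNet",
    "build_model",
    "count_parameters",
    "make_ablation_suite",
    "ABLATION_NAMES",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_MAGIC",
]

CHECKPOINT_MAGIC = "WAVESEG.v1"

ABLATION_NAMES = (
    "baseline",
    "+wtconv",
    "+wcf",
    "+lrfa",
    "full-lrfa",
    "full-wtconv",
    "full-wcf",
    "full",
)


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 3
    num_classes: int = 1
    base_width: int = 32
    num_stages: int = 5
    wtconv_stages: frozenset[int] = frozenset({4, 5})
    lrfa_stages: frozenset[int] = frozenset({5})
    use_wcf: bool = True
    upsample_mode: str = "bilinear"  # "bilinear" (bilinear + 1x1) or "transpose"
    image_size: int = 256
    lrfa_num_heads: int = 4
    lrfa_max_tokens: int = 1024
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "wtconv_stages", frozenset(self.wtconv_stages))
        object.__setattr__(self, "lrfa_stages", frozenset(self.lrfa_stages))

    def stage_width(self, stage: int) -> int:
        return self.base_width * 2 ** (stage - 1)

    def stage_size(self, stage: int) -> int:
        return self.image_size // 2 ** (stage - 1)

    def validate(self) -> None:
        stages = set(range(1, self.num_stages + 1))
        if self.num_stages < 2:
            raise ConfigurationError("need at least 2 stages")
        if not set(self.wtconv_stages) <= stages:
            raise ConfigurationError(
                f"wtconv_stages {sorted(self.wtconv_stages)} outside 1..{self.num_stages}"
            )
        if not set(self.lrfa_stages) <= stages:
            raise ConfigurationError(
                f"lrfa_stages {sorted(self.lrfa_stages)} outside 1..{self.num_stages}"
            )
        divisor = 2 ** (self.num_stages - 1)
        if self.image_size % divisor:
            raise ConfigurationError(
                f"image_size {self.image_size} must be divisible by {divisor}"
            )
        if self.stage_size(self.num_stages) < 4:
            raise ConfigurationError(
                f"deepest stage spatial size {self.stage_size(self.num_stages)} < 4 "
                f"for image_size {self.image_size}"
            )
        for s in self.lrfa_stages:
            tokens = self.stage_size(s) ** 2
            if tokens > self.lrfa_max_tokens:
                raise ConfigurationError(
                    f"LRFA at stage {s} would see {tokens} tokens "
                    f"(> max_tokens {self.lrfa_max_tokens}); use a deeper stage"
                )
            if self.stage_width(s) % self.lrfa_num_heads:
                raise ConfigurationError(
                    f"stage {s} width {self.stage_width(s)} not divisible by "
                    f"{self.lrfa_num_heads} attention heads"
                )
        if self.upsample_mode not in ("bilinear", "transpose"):
            raise ConfigurationError(f"unknown upsample_mode {self.upsample_mode!r}")


def _conv_block(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        Conv2d(cin, cout, 3, rng), GroupNorm2d(cout), GELU(),
        Conv2d(cout, cout, 3, rng), GroupNorm2d(cout), GELU(),
    )


class _Upsampler(Module):
    """2x spatial upsampling with channel halving.

    ``bilinear`` mode: bilinear interpolation followed by a 1x1 conv.
    ``transpose`` mode: zero-stuffing followed by a 3x3 conv (a
    fractionally-strided convolution).
    """

    def __init__(self, cin: int, cout: int, mode: str, rng: np.random.Generator):
        self.mode = mode
        self.conv = Conv2d(cin, cout, 1 if mode == "bilinear" else 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.mode == "bilinear":
            return self.conv(ag.upsample_bilinear2x(x))
        zeros = Tensor(np.zeros(x.shape))
        stuffed = ag.interleave2x2(x, zeros, zeros, zeros)
        return self.conv(stuffed)


class SegmentationUNet(Module):
    def __init__(self, cfg: ModelConfig):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ns = cfg.num_stages
        widths = [cfg.stage_width(s) for s in range(1, ns + 1)]

        self.encoder = ModuleList()
        self.enc_extras = ModuleList()  # wavelet / attention blocks per stage
        cin = cfg.in_channels
        for s, w in enumerate(widths, start=1):
            self.encoder.append(_conv_block(cin, w, rng))
            extras = ModuleList()
            if s in cfg.wtconv_stages:
                extras.append(WtConv(w, rng=rng))
            if s in cfg.lrfa_stages:
                lrfa_cfg = LRFAConfig(
                    channels=w, num_heads=cfg.lrfa_num_heads, max_tokens=cfg.lrfa_max_tokens
                )
                extras.append(LRFA(lrfa_cfg, rng=rng))
            self.enc_extras.append(extras)
            cin = w

        self.upsamplers = ModuleList()
        self.fusions = ModuleList()  # WCF blocks or 1x1 concat-merge convs
        self.decoder = ModuleList()
        for s in range(ns - 1, 0, -1):  # deep -> shallow
            w_deep, w = widths[s], widths[s - 1]
            self.upsamplers.append(_Upsampler(w_deep, w, cfg.upsample_mode, rng))
            if cfg.use_wcf:
                self.fusions.append(WCF(w, rng=rng))
            else:
                self.fusions.append(Conv2d(2 * w, w, 1, rng))
            self.decoder.append(_conv_block(w, w, rng))

        self.head = Conv2d(widths[0], cfg.num_classes, 1, rng)

    def forward(self, images: Tensor | np.ndarray) -> Tensor:
        x = as_tensor(images)
        if x.ndim != 4 or x.shape[1] != self.cfg.in_channels:
            raise ValidationError(
                f"expected (B,{self.cfg.in_channels},H,W) input, got {x.shape}"
            )
        divisor = 2 ** (self.cfg.num_stages - 1)
        _, _, H, W = x.shape
        if H % divisor or W % divisor:
            raise ValidationError(
                f"spatial size {H}x{W} must be divisible by {divisor} "
                f"for a {self.cfg.num_stages}-stage model"
            )
        skips = []
        for i, (block, extras) in enumerate(zip(self.encoder, self.enc_extras)):
            if i > 0:
                x = ag.maxpool2x2(x)
            x = block(x)
            for extra in extras:
                x = extra(x)
            skips.append(x)
        for up, fusion, dec, skip in zip(
            self.upsamplers, self.fusions, self.decoder, reversed(skips[:-1])
        ):
            x = up(x)
            if self.cfg.use_wcf:
                x = fusion(skip, x)  # x1 = encoder skip, x2 = upsampled decoder
            else:
                x = fusion(ag.concat([skip, x], axis=1))
            x = dec(x)
        logits = self.head(x)
        if self.cfg.num_classes == 1:
            return logits.sigmoid()
        return ag.softmax(logits, axis=1)


def build_model(cfg: ModelConfig) -> SegmentationUNet:
    return SegmentationUNet(cfg)


def count_parameters(model: Module) -> int:
    return int(sum(p.data.size for p in model.parameters()))


@dataclass(frozen=True)
class AblationVariant:
    name: str
    config: ModelConfig

    @property
    def module_set(self) -> frozenset[str]:
        mods = set()
        if self.config.wtconv_stages:
            mods.add("wtconv")
        if self.config.lrfa_stages:
            mods.add("lrfa")
        if self.config.use_wcf:
            mods.add("wcf")
        return frozenset(mods)


def make_ablation_suite(base: ModelConfig) -> list[AblationVariant]:
    """The eight standard ablation variants derived from the full config."""
    none_wt: frozenset[int] = frozenset()
    rows = {
        "baseline": dict(wtconv_stages=none_wt, lrfa_stages=none_wt, use_wcf=False),
        "+wtconv": dict(wtconv_stages=base.wtconv_stages, lrfa_stages=none_wt, use_wcf=False),
        "+wcf": dict(wtconv_stages=none_wt, lrfa_stages=none_wt, use_wcf=True),
        "+lrfa": dict(wtconv_stages=none_wt, lrfa_stages=base.lrfa_stages, use_wcf=False),
        "full-lrfa": dict(wtconv_stages=base.wtconv_stages, lrfa_stages=none_wt, use_wcf=True),
        "full-wtconv": dict(wtconv_stages=none_wt, lrfa_stages=base.lrfa_stages, use_wcf=True),
        "full-wcf": dict(
            wtconv_stages=base.wtconv_stages, lrfa_stages=base.lrfa_stages, use_wcf=False
        ),
        "full": dict(
            wtconv_stages=base.wtconv_stages, lrfa_stages=base.lrfa_stages, use_wcf=True
        ),
    }
    return [AblationVariant(name, replace(base, **kw)) for name, kw in rows.items()]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def _config_to_json(cfg: ModelConfig) -> str:
    d = asdict(cfg)
    d["wtconv_stages"] = sorted(d["wtconv_stages"])
    d["lrfa_stages"] = sorted(d["lrfa_stages"])
    return json.dumps(d)


def _config_from_json(s: str) -> ModelConfig:
    d = json.loads(s)
    d["wtconv_stages"] = frozenset(d["wtconv_stages"])
    d["lrfa_stages"] = frozenset(d["lrfa_stages"])
    return ModelConfig(**d)


def save_checkpoint(path: str | Path, model: SegmentationUNet,
                    optimizer_state: dict | None = None, epoch: int = 0) -> None:
    """Single-archive checkpoint: magic string, config, weights, optimizer, epoch."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if optimizer_state is not None:
        arrays["opt/t"] = np.asarray(optimizer_state["t"])
        for i, m in enumerate(optimizer_state["m"]):
            arrays[f"opt/m{i}"] = m
        for i, v in enumerate(optimizer_state["v"]):
            arrays[f"opt/v{i}"] = v
    np.savez(
        path,
        magic=np.array(CHECKPOINT_MAGIC),
        config=np.array(_config_to_json(model.cfg)),
        epoch=np.asarray(epoch),
        **arrays,
    )


def load_checkpoint(path: str | Path):
    """Returns ``(model, optimizer_state_or_None, epoch)``."""
    with np.load(path, allow_pickle=False) as z:
        magic = str(z["magic"])
        if magic != CHECKPOINT_MAGIC:
            raise ValidationError(f"not a recognised checkpoint (magic {magic!r})")
        cfg = _config_from_json(str(z["config"]))
        model = build_model(cfg)
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        model.load_state_dict(state)
        epoch = int(z["epoch"])
        opt_state = None
        if "opt/t" in z.files:
            n = len(model.parameters())
            opt_state = {
                "t": int(z["opt/t"]),
                "m": [z[f"opt/m{i}"] for i in range(n)],
                "v": [z[f"opt/v{i}"] for i in range(n)],
            }
    return model, opt_state, epoch
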