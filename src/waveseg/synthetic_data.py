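"""Deterministic synthetic image/mask pairs for four challenge regimes.

Real segmentation benchmarks for this kind of model span endoscopic polyps,
dermoscopic lesions, thyroid-nodule ultrasound and dental radiographs.  The
generator emulates the *stated difficulty* of each modality rather than its
photometric appearance:

``polyp`` / ``lesion``
    one to three smooth blobs (Fourier-perturbed ellipses); the lesion
    regime uses lower contrast and a wider boundary blur, so edges are
    indistinct while the reference mask (the pre-blur geometry) stays crisp
    — mirroring how human annotators draw sharp contours over fuzzy tissue.
``ultrasound``
    the same geometry at low contrast with multiplicative speckle noise.
``tooth``
    a row of rounded rectangles repeated at a fixed period with 1–2 px
    gaps: high-density, finely structured, densely packed targets.

Spatial parameters (blur sigma, structure period) are specified at a
256-px reference scale and scaled proportionally for other image sizes, so
a 64-px desk-scale sample presents the same relative difficulty.

Every sample is a pure function of ``(spec, seed, index)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .errors import GenerationError, ValidationError

__all__ = ["RegimeSpec", "SamplePair", "generate_sample", "generate_dataset", "REGIMES"]

REGIMES = ("polyp", "lesion", "ultrasound", "tooth")

_REFERENCE_SIZE = 256

# per-regime defaults at the 256-px reference scale
_PRESETS = {
    "polyp": dict(object_count_range=(1, 3), contrast=0.45, boundary_blur_sigma=1.5,
                  speckle_strength=0.0, structure_period=0),
    "lesion": dict(object_count_range=(1, 3), contrast=0.35, boundary_blur_sigma=3.0,
                   speckle_strength=0.0, structure_period=0),
    "ultrasound": dict(object_count_range=(1, 2), contrast=0.2, boundary_blur_sigma=2.0,
                       speckle_strength=0.3, structure_period=0),
    "tooth": dict(object_count_range=(4, 8), contrast=0.5, boundary_blur_sigma=1.0,
                  speckle_strength=0.0, structure_period=18),
}

_FG_FRACTION_BOUNDS = (0.005, 0.6)
_TEXTURE_SIGMA = 0.02  # additive texture noise, clipped to +-0.12
_BACKGROUND_LEVEL = 0.32
_CHANNEL_TINTS = {
    "polyp": (1.0, 0.82, 0.78),
    "lesion": (1.0, 0.9, 0.8),
    "ultrasound": (1.0, 1.0, 1.0),
    "tooth": (1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class RegimeSpec:
    regime: str
    image_size: int = 256
    object_count_range: tuple[int, int] = (1, 3)
    contrast: float = 0.45
    boundary_blur_sigma: float = 1.5
    speckle_strength: float = 0.0
    structure_period: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValidationError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if not (0.0 < self.contrast <= 1.0):
            raise ValidationError("contrast must lie in (0, 1]")
        if self.image_size <= 0 or self.speckle_strength < 0 or self.boundary_blur_sigma < 0:
            raise ValidationError("sizes must be positive and noise levels non-negative")

    @classmethod
    def preset(cls, regime: str, image_size: int = 256, **overrides) -> "RegimeSpec":
        """Regime defaults with spatial parameters rescaled to ``image_size``."""
        base = dict(_PRESETS[regime])
        scale = image_size / _REFERENCE_SIZE
        base["boundary_blur_sigma"] = base["boundary_blur_sigma"] * scale
        if base["structure_period"]:
            base["structure_period"] = max(4, round(base["structure_period"] * scale))
        base.update(overrides)
        return cls(regime=regime, image_size=image_size, **base)


@dataclass
class SamplePair:
    image: np.ndarray  # (3, H, W) float64 in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    meta: dict = field(default_factory=dict)


def _blob_mask(size: int, rng: np.random.Generator, n_objects: int) -> np.ndarray:
    """Union of Fourier-perturbed ellipses."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(n_objects):
        cy, cx = rng.uniform(0.2 * size, 0.8 * size, size=2)
        r0 = rng.uniform(0.10, 0.24) * size
        aspect = rng.uniform(0.6, 1.0)
        theta0 = rng.uniform(0, 2 * np.pi)
        amps = rng.normal(0.0, 0.07, size=4)
        phases = rng.uniform(0, 2 * np.pi, size=4)
        dy, dx = yy - cy, xx - cx
        # rotate into the ellipse frame
        ry = np.cos(theta0) * dy - np.sin(theta0) * dx
        rx = np.sin(theta0) * dy + np.cos(theta0) * dx
        dist = np.sqrt((ry / aspect) ** 2 + rx**2)
        ang = np.arctan2(ry, rx)
        radius = r0 * (
            1.0 + sum(a * np.cos((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amps, phases)))
        )
        mask |= dist < np.maximum(radius, 2.0)
    return mask


def _tooth_mask(size: int, rng: np.random.Generator, period: int) -> np.ndarray:
    """Row of rounded rectangles at fixed period with 1-2 px gaps."""
    mask = np.zeros((size, size), dtype=bool)
    gap = int(rng.integers(1, 3))
    width = max(2, period - gap)
    height = rng.uniform(0.4, 0.6) * size
    top = (size - height) / 2 + rng.uniform(-0.05, 0.05) * size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x0 = rng.integers(0, max(1, period))
    for left in range(int(x0), size - 1, max(4, period)):
        right = min(left + width, size)
        cx = (left + right) / 2
        cy = top + height / 2
        hw = (right - left) / 2
        hh = height / 2
        r = min(hw, hh) * 0.5  # corner rounding radius
        inx = np.abs(xx - cx) <= hw
        iny = np.abs(yy - cy) <= hh
        core = inx & iny
        # carve corners: keep points within distance r of the inset rectangle
        ex = np.maximum(np.abs(xx - cx) - (hw - r), 0.0)
        ey = np.maximum(np.abs(yy - cy) - (hh - r), 0.0)
        rounded = core & (ex**2 + ey**2 <= r**2)
        mask |= rounded
    return mask


def _render_image(mask: np.ndarray, spec: RegimeSpec, rng: np.random.Generator) -> np.ndarray:
    size = spec.image_size
    intensity = _BACKGROUND_LEVEL + spec.contrast * mask.astype(np.float64)
    if spec.boundary_blur_sigma > 0:
        intensity = gaussian_filter(intensity, spec.boundary_blur_sigma, mode="nearest")
    texture = np.clip(rng.normal(0.0, _TEXTURE_SIGMA, size=(size, size)), -0.12, 0.12)
    intensity = intensity + texture
    if spec.speckle_strength > 0:
        speckle = rng.normal(0.0, np.sqrt(spec.speckle_strength), size=(size, size))
        intensity = intensity * (1.0 + speckle)
    intensity = np.clip(intensity, 0.0, 1.0)
    tints = np.array(_CHANNEL_TINTS[spec.regime]).reshape(3, 1, 1)
    return np.clip(intensity[None, :, :] * tints, 0.0, 1.0)


def generate_sample(spec: RegimeSpec, seed: int, index: int) -> SamplePair:
    """One image/mask pair, fully determined by ``(spec, seed, index)``."""
    regime_code = REGIMES.index(spec.regime)
    lo, hi = _FG_FRACTION_BOUNDS
    for attempt in range(100):
        rng = np.random.default_rng([regime_code, seed, index, attempt])
        if spec.regime == "tooth":
            mask = _tooth_mask(spec.image_size, rng, spec.structure_period)
        else:
            n_objects = int(rng.integers(spec.object_count_range[0],
                                         spec.object_count_range[1] + 1))
            mask = _blob_mask(spec.image_size, rng, n_objects)
        frac = mask.mean()
        if lo < frac < hi:
            image = _render_image(mask, spec, rng)
            meta = {"regime": spec.regime, "seed": seed, "index": index}
            return SamplePair(image=image, mask=mask.astype(np.uint8), meta=meta)
    raise GenerationError(
        f"could not satisfy foreground fraction {_FG_FRACTION_BOUNDS} "
        f"after 100 attempts for spec {spec}"
    )


def generate_dataset(spec: RegimeSpec, n: int, seed: int, out_dir: str | Path) -> dict:
    """Write ``n`` PNG pairs plus a JSON manifest; returns the manifest.

    Images are 8-bit RGB; masks are 8-bit single-channel with values {0, 255}
    (PNG is lossless, so masks round-trip exactly).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    pairs = []
    for i in range(n):
        sample = generate_sample(spec, seed, i)
        img8 = np.round(sample.image * 255.0).astype(np.uint8).transpose(1, 2, 0)
        mask8 = (sample.mask * 255).astype(np.uint8)
        image_rel = f"images/{i:05d}.png"
        mask_rel = f"masks/{i:05d}.png"
        Image.fromarray(img8, mode="RGB").save(out_dir / image_rel)
        Image.fromarray(mask8, mode="L").save(out_dir / mask_rel)
        pairs.append({"index": i, "image": image_rel, "mask": mask_rel})
    manifest = {
        "regime": spec.regime,
        "seed": seed,
        "image_size": spec.image_size,
        "pairs": pairs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
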