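"""Training, cross-validation and ablation orchestration.

The training recipe: AdamW (initial learning rate 1e-4, weight decay 1e-5),
a single-cycle cosine annealing of the learning rate per epoch down to
1e-6, hybrid Dice + cross-entropy loss, batch size 8, 200 epochs, and
five-fold cross-validation.  Augmentation applies one geometric transform
to image and mask jointly: random rotation (+-15 deg), horizontal/vertical
flips (p = 0.5 each), scaling (0.8-1.2x) and an elastic displacement field;
images are interpolated bilinearly, masks with nearest-neighbour and
re-binarized.

Channel standardisation statistics are computed on the training portion
only and applied to held-out data, so cross-validation folds never leak.
Runs are fully deterministic under a fixed seed: all randomness flows from
seeded NumPy generators and the compute engine is single-threaded NumPy.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import map_coordinates, zoom

from .autograd import Tensor, no_grad
from .errors import ValidationError
from .losses_metrics import (LossConfig, MetricsReport, evaluate_masks, hybrid_loss)
from .network import (ModelConfig, SegmentationUNet, build_model,
                      make_ablation_suite, save_checkpoint)
from .optim import AdamW, cosine_lr
from .synthetic_data import SamplePair

__all__ = [
    "TrainConfig",
    "FoldResult",
    "load_dataset",
    "augment",
    "run_training",
    "run_cross_validation",
    "run_ablation",
    "predict_masks",
]

BINARIZE_THRESHOLD = 0.5


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 200
    batch_size: int = 8
    lr_min: float = 1e-6
    folds: int = 5
    image_size: int = 256
    seed: int = 0
    # augmentation toggles and ranges
    augment: bool = True
    rotation: bool = True
    rotation_deg: float = 15.0
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    scaling: bool = True
    scale_min: float = 0.8
    scale_max: float = 1.2
    elastic: bool = True
    elastic_sigma: float = 6.0  # displacement smoothness, px
    elastic_alpha: float = 20.0  # displacement magnitude, px
    elastic_grid: int = 8  # coarse displacement grid resolution
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self):
        if self.epochs < 1 or self.folds < 2 or self.batch_size < 1:
            raise ValidationError("epochs >= 1, folds >= 2, batch_size >= 1 required")
        if not (0.0 < self.lr_min < self.lr):
            raise ValidationError("need 0 < lr_min < lr")


@dataclass
class FoldResult:
    fold_index: int
    loss_history: list[float]
    best_metrics: MetricsReport
    checkpoint_path: Path | None
    val_indices: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# dataset I/O
# ---------------------------------------------------------------------------


def _list_pairs(root: Path) -> list[tuple[Path, Path]]:
    manifest = root / "manifest.json"
    if manifest.exists():
        with open(manifest) as fh:
            m = json.load(fh)
        return [(root / p["image"], root / p["mask"]) for p in m["pairs"]]
    img_dir, mask_dir = root / "images", root / "masks"
    if not img_dir.is_dir() or not mask_dir.is_dir():
        raise ValidationError(f"{root} lacks an images/masks layout or manifest.json")
    pairs = []
    for img in sorted(img_dir.iterdir()):
        mask = mask_dir / img.name
        if not mask.exists():
            raise ValidationError(f"image without matching mask: {img.name}")
        pairs.append((img, mask))
    return pairs


def load_dataset(data_dir: str | Path, image_size: int,
                 normalize: bool = True) -> list[SamplePair]:
    """Load image/mask pairs, resize, optionally standardise image channels.

    Images resize bilinearly; masks resize nearest-neighbour and are
    re-binarized.  With ``normalize`` the whole collection is standardised
    per channel (dataset mean 0, std 1).
    """
    root = Path(data_dir)
    pairs = _list_pairs(root)
    samples: list[SamplePair] = []
    for img_path, mask_path in pairs:
        img = Image.open(img_path).convert("RGB")
        mask_img = Image.open(mask_path).convert("L")
        mask_arr = np.asarray(mask_img)
        if not np.isin(mask_arr, (0, 255)).all():
            raise ValidationError(
                f"mask {mask_path.name} has values outside {{0, 255}} after load"
            )
        img = img.resize((image_size, image_size), Image.BILINEAR)
        mask_img = mask_img.resize((image_size, image_size), Image.NEAREST)
        image = np.asarray(img, dtype=np.float64).transpose(2, 0, 1) / 255.0
        mask = (np.asarray(mask_img) > 127).astype(np.uint8)
        samples.append(SamplePair(image=image, mask=mask,
                                  meta={"source": img_path.name}))
    if normalize:
        mean, std = channel_stats(samples)
        samples = [replace_image(s, (s.image - mean) / std) for s in samples]
    return samples


def channel_stats(samples: list[SamplePair]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and std over all pixels of a sample collection."""
    stacked = np.stack([s.image for s in samples])  # (N, 3, H, W)
    mean = stacked.mean(axis=(0, 2, 3), keepdims=False).reshape(3, 1, 1)
    std = stacked.std(axis=(0, 2, 3), keepdims=False).reshape(3, 1, 1)
    std = np.where(std < 1e-8, 1.0, std)
    return mean, std


def replace_image(sample: SamplePair, image: np.ndarray) -> SamplePair:
    return SamplePair(image=image, mask=sample.mask, meta=dict(sample.meta))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _elastic_field(size: int, cfg: TrainConfig, rng: np.random.Generator):
    coarse = rng.normal(0.0, 1.0, size=(2, cfg.elastic_grid, cfg.elastic_grid))
    factor = size / cfg.elastic_grid
    disp = np.stack([zoom(c, factor, order=3) for c in coarse])[:, :size, :size]
    # smooth and scale to the requested displacement magnitude
    from scipy.ndimage import gaussian_filter

    disp = np.stack([gaussian_filter(d, cfg.elastic_sigma, mode="reflect") for d in disp])
    for d in disp:
        peak = np.abs(d).max()
        if peak > 0:
            d *= 1.0 / peak
    return disp * cfg.elastic_alpha


def augment(pair: SamplePair, cfg: TrainConfig, rng: np.random.Generator) -> SamplePair:
    """One random geometric transform applied identically to image and mask.

    With every transform disabled (or ``cfg.augment`` off) the input is
    returned unchanged, bit for bit.
    """
    if not cfg.augment:
        return pair
    image, mask = pair.image, pair.mask
    size = mask.shape[-1]

    do_hflip = cfg.hflip_p > 0 and rng.random() < cfg.hflip_p
    do_vflip = cfg.vflip_p > 0 and rng.random() < cfg.vflip_p
    angle = rng.uniform(-cfg.rotation_deg, cfg.rotation_deg) if cfg.rotation else 0.0
    scale = rng.uniform(cfg.scale_min, cfg.scale_max) if cfg.scaling else 1.0
    disp = _elastic_field(size, cfg, rng) if cfg.elastic else None

    if do_hflip:
        image = image[:, :, ::-1]
        mask = mask[:, ::-1]
    if do_vflip:
        image = image[:, ::-1, :]
        mask = mask[::-1, :]

    if angle != 0.0 or scale != 1.0 or disp is not None:
        c = (size - 1) / 2.0
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        if disp is not None:
            yy = yy + disp[0]
            xx = xx + disp[1]
        th = np.deg2rad(angle)
        # inverse map: rotate by -angle and divide by scale about the centre
        ys = (np.cos(th) * (yy - c) + np.sin(th) * (xx - c)) / scale + c
        xs = (-np.sin(th) * (yy - c) + np.cos(th) * (xx - c)) / scale + c
        coords = np.stack([ys, xs])
        image = np.stack([
            map_coordinates(ch, coords, order=1, mode="reflect") for ch in image
        ])
        mask_f = map_coordinates(mask.astype(np.float64), coords, order=0, mode="reflect")
        mask = (mask_f > 0.5).astype(np.uint8)
    else:
        image = np.ascontiguousarray(image)
        mask = np.ascontiguousarray(mask)

    return SamplePair(image=image, mask=mask, meta=dict(pair.meta))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


class _RunLogger:
    def __init__(self, out_dir: Path | None, name: str):
        self.text = None
        self.jsonl = None
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            self.text = open(out_dir / f"{name}.log", "a")
            self.jsonl = open(out_dir / f"{name}.epochs.jsonl", "a")

    def log(self, msg: str) -> None:
        if self.text:
            stamp = time.strftime("%Y-%m-%d %H:%M:%S")
            self.text.write(f"[{stamp}] {msg}\n")
            self.text.flush()

    def epoch(self, record: dict) -> None:
        if self.jsonl:
            self.jsonl.write(json.dumps(record) + "\n")
            self.jsonl.flush()

    def close(self) -> None:
        for fh in (self.text, self.jsonl):
            if fh:
                fh.close()


def _resolve_samples(data, image_size: int) -> list[SamplePair]:
    if isinstance(data, (str, Path)):
        return load_dataset(data, image_size, normalize=False)
    return list(data)


def _predict_batch(model: SegmentationUNet, images: np.ndarray) -> np.ndarray:
    with no_grad():
        return model(Tensor(images)).data


def predict_masks(model: SegmentationUNet, samples: list[SamplePair],
                  batch_size: int = 8) -> list[np.ndarray]:
    """Thresholded (0.5) binary predictions for a list of samples."""
    out = []
    for i in range(0, len(samples), batch_size):
        batch = np.stack([s.image for s in samples[i:i + batch_size]])
        probs = _predict_batch(model, batch)
        out.extend((probs[:, 0] > BINARIZE_THRESHOLD).astype(np.uint8))
    return out


def run_training(model_cfg: ModelConfig, train_cfg: TrainConfig, data,
                 out_dir: str | Path | None = None,
                 train_indices: list[int] | None = None,
                 val_indices: list[int] | None = None,
                 fold_index: int = 0,
                 max_steps: int | None = None,
                 eval_every: int = 1,
                 stop_at_dice: float | None = None,
                 run_name: str = "train") -> FoldResult:
    """Train one model; returns loss history and best held-out metrics.

    ``data`` is a dataset directory or a list of (unnormalised) samples.
    Without explicit index lists the whole set is both trained and evaluated
    on (desk-scale learnability checks).  ``max_steps`` caps total optimizer
    steps for reduced runs.
    """
    samples = _resolve_samples(data, train_cfg.image_size)
    if not samples:
        raise ValidationError("dataset is empty")
    n = len(samples)
    train_indices = list(range(n)) if train_indices is None else list(train_indices)
    eval_indices = train_indices if val_indices is None else list(val_indices)

    train_samples = [samples[i] for i in train_indices]
    mean, std = channel_stats(train_samples)
    norm = [replace_image(s, (s.image - mean) / std) for s in samples]
    eval_samples = [norm[i] for i in eval_indices]
    eval_masks = [s.mask for s in eval_samples]

    model_cfg = replace(model_cfg, image_size=train_cfg.image_size)
    model = build_model(model_cfg)
    opt = AdamW(model.parameters(), lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng([train_cfg.seed, fold_index])

    out_dir = Path(out_dir) if out_dir is not None else None
    logger = _RunLogger(out_dir, run_name)
    logger.log(f"fold {fold_index}: {len(train_indices)} train / {len(eval_indices)} eval "
               f"samples, {train_cfg.epochs} epochs, batch {train_cfg.batch_size}")

    loss_history: list[float] = []
    best = MetricsReport(-1.0, 0.0, 0.0, 0.0, n_images=0)
    ckpt_path = out_dir / f"{run_name}_fold{fold_index}.npz" if out_dir else None
    steps = 0
    stop = False
    for epoch in range(train_cfg.epochs):
        opt.lr = cosine_lr(epoch, train_cfg.epochs, train_cfg.lr, train_cfg.lr_min)
        order = rng.permutation(len(train_indices))
        epoch_losses = []
        for b0 in range(0, len(order), train_cfg.batch_size):
            batch_ids = order[b0:b0 + train_cfg.batch_size]
            batch = [augment(norm[train_indices[i]], train_cfg, rng) for i in batch_ids]
            images = np.stack([s.image for s in batch])
            masks = np.stack([s.mask for s in batch])[:, None, :, :].astype(np.float64)
            probs = model(Tensor(images))
            loss = hybrid_loss(probs, masks, train_cfg.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at {b0}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(value)
            loss_history.append(value)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                stop = True
                break
        is_last = stop or epoch == train_cfg.epochs - 1
        if is_last or (epoch % eval_every == 0):
            preds = predict_masks(model, eval_samples, train_cfg.batch_size)
            report, _ = evaluate_masks(preds, eval_masks)
            logger.epoch({"epoch": epoch, "lr": opt.lr,
                          "loss": float(np.mean(epoch_losses)) if epoch_losses else None,
                          "val_dice": report.dsc})
            if report.dsc > best.dsc:
                best = report
                if ckpt_path is not None:
                    save_checkpoint(ckpt_path, model, opt.state_dict(), epoch)
            if stop_at_dice is not None and best.dsc >= stop_at_dice:
                stop = True
        if stop:
            break
    logger.log(f"fold {fold_index}: best dice {best.dsc:.4f} over {steps} steps")
    logger.close()
    result = FoldResult(fold_index, loss_history, best, ckpt_path,
                        val_indices=list(eval_indices))
    result.model = model  # type: ignore[attr-defined]  # handy for desk-scale checks
    return result


def make_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded partition of range(n) into ``folds`` disjoint held-out sets."""
    if n < folds:
        raise ValidationError(f"dataset of {n} samples cannot form {folds} folds")
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def split_hash(parts: list[np.ndarray]) -> str:
    h = hashlib.sha1()
    for p in parts:
        h.update(np.asarray(p, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:12]


def run_cross_validation(model_cfg: ModelConfig, train_cfg: TrainConfig, data,
                         out_dir: str | Path | None = None,
                         max_steps: int | None = None,
                         eval_every: int = 1):
    """K-fold CV; returns ``(fold_results, aggregate)`` with mean/std per metric."""
    samples = _resolve_samples(data, train_cfg.image_size)
    parts = make_folds(len(samples), train_cfg.folds, train_cfg.seed)
    all_idx = set(range(len(samples)))
    results = []
    for k, held_out in enumerate(parts):
        val_idx = [int(i) for i in held_out]
        train_idx = sorted(all_idx - set(val_idx))
        results.append(
            run_training(model_cfg, train_cfg, samples, out_dir=out_dir,
                         train_indices=train_idx, val_indices=val_idx,
                         fold_index=k, max_steps=max_steps, eval_every=eval_every,
                         run_name="cv")
        )
    aggregate = {}
    for metric in ("dsc", "iou", "precision", "sensitivity"):
        vals = np.array([getattr(r.best_metrics, metric) for r in results])
        aggregate[metric] = (float(vals.mean()), float(vals.std()))
    return results, aggregate


def run_ablation(base_model_cfg: ModelConfig, train_cfg: TrainConfig, data,
                 out_dir: str | Path | None = None,
                 max_steps: int | None = None,
                 eval_every: int = 10**9) -> pd.DataFrame:
    """Train all eight ablation variants under an identical split and seed.

    Returns (and optionally writes) a table with one row per variant:
    variant, dice, iou, precision, sensitivity, plus the shared split hash.
    """
    samples = _resolve_samples(data, train_cfg.image_size)
    parts = make_folds(len(samples), train_cfg.folds, train_cfg.seed)
    val_idx = [int(i) for i in parts[0]]
    train_idx = sorted(set(range(len(samples))) - set(val_idx))
    shash = split_hash(parts)
    rows = []
    for variant in make_ablation_suite(base_model_cfg):
        res = run_training(variant.config, train_cfg, samples, out_dir=out_dir,
                           train_indices=train_idx, val_indices=val_idx,
                           max_steps=max_steps, eval_every=eval_every,
                           run_name=f"ablate_{variant.name}")
        m = res.best_metrics
        rows.append({"variant": variant.name, "dice": m.dsc, "iou": m.iou,
                     "precision": m.precision, "sensitivity": m.sensitivity,
                     "split_hash": shash})
    df = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_dir / "ablation.csv", index=False)
    return df
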