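"""Hybrid Dice + cross-entropy training loss and overlap evaluation metrics.

Training loss (binary foreground segmentation):

    L_total = lambda_ce * L_CE + lambda_dice * L_Dice

with L_CE the mean binary cross-entropy over pixels (probabilities clamped
to [eps, 1-eps], eps = 1e-7) and L_Dice = 1 - (2*sum(p*t) + s) / (sum(p) +
sum(t) + s) computed per image and averaged; the smoothing constant s
(default 1.0) keeps the loss defined for empty masks.  Defaults
lambda_ce = 0.4, lambda_dice = 0.6 weight overlap above per-pixel accuracy,
which helps small targets and fine boundaries.

Evaluation metrics use exact integer confusion counts (no smoothing):

    DSC = 2TP / (2TP + FP + FN)          IoU = TP / (TP + FP + FN)
    Precision = TP / (TP + FP)           Sensitivity = TP / (TP + FN)

Degenerate denominators: when TP = FP = FN = 0 (both masks empty) every
metric is 1 (perfect agreement on absence); when only a denominator
vanishes with disagreement present, the metric is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .autograd import Tensor, as_tensor
from .errors import ValidationError

__all__ = [
    "LossConfig",
    "ConfusionCounts",
    "MetricsReport",
    "bce_loss",
    "dice_loss",
    "hybrid_loss",
    "confusion_counts",
    "compute_metrics",
    "evaluate_masks",
    "metrics_to_csv",
    "EPS_CLAMP",
]

EPS_CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    lambda_ce: float = 0.4
    lambda_dice: float = 0.6
    smooth: float = 1.0

    def __post_init__(self):
        if self.lambda_ce < 0 or self.lambda_dice < 0 or self.lambda_ce + self.lambda_dice <= 0:
            raise ValidationError("loss weights must be non-negative with a positive sum")


def _validate_pair(probs: Tensor, target: np.ndarray) -> np.ndarray:
    target = np.asarray(target, dtype=np.float64)
    if probs.shape != target.shape:
        raise ValidationError(f"shape mismatch: probs {probs.shape} vs target {target.shape}")
    if not np.isin(target, (0.0, 1.0)).all():
        raise ValidationError("target mask must be binary (0/1)")
    return target


def bce_loss(probs: Tensor | np.ndarray, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over all pixels, probabilities clamped."""
    probs = as_tensor(probs)
    target = _validate_pair(probs, target)
    p = probs.clip(EPS_CLAMP, 1.0 - EPS_CLAMP)
    losses = -(Tensor(target) * p.log() + Tensor(1.0 - target) * (1.0 - p).log())
    return losses.mean()


def dice_loss(probs: Tensor | np.ndarray, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss computed per image (first axis) and averaged."""
    probs = as_tensor(probs)
    target = _validate_pair(probs, target)
    n = probs.shape[0]
    axes = tuple(range(1, probs.ndim))
    t = Tensor(target)
    inter = (probs * t).sum(axis=axes)
    denom = probs.sum(axis=axes) + t.sum(axis=axes)
    dice = (inter * 2.0 + smooth) / (denom + smooth)
    return (1.0 - dice).sum() * (1.0 / n)


def hybrid_loss(probs: Tensor | np.ndarray, target_mask: np.ndarray,
                cfg: LossConfig = LossConfig()) -> Tensor:
    """Weighted sum of cross-entropy and Dice losses."""
    probs = as_tensor(probs)
    return bce_loss(probs, target_mask) * cfg.lambda_ce + dice_loss(
        probs, target_mask, cfg.smooth
    ) * cfg.lambda_dice


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class MetricsReport:
    dsc: float
    iou: float
    precision: float
    sensitivity: float
    n_images: int = 1
    aggregation: str = "per_image_mean"


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary masks.

    Inputs must already be binary; thresholding probabilities at 0.5 is the
    pipeline's responsibility, not this function's.
    """
    pred = np.asarray(pred_mask)
    gt = np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    for name, m in (("pred_mask", pred), ("gt_mask", gt)):
        if not np.isin(m, (0, 1)).all():
            raise ValidationError(f"{name} must be binary (0/1)")
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int, all_empty: bool) -> float:
    if den == 0:
        return 1.0 if all_empty else 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    all_empty = tp == 0 and fp == 0 and fn == 0
    return MetricsReport(
        dsc=_ratio(2 * tp, 2 * tp + fp + fn, all_empty),
        iou=_ratio(tp, tp + fp + fn, all_empty),
        precision=_ratio(tp, tp + fp, all_empty),
        sensitivity=_ratio(tp, tp + fn, all_empty),
        n_images=1,
        aggregation="single",
    )


def evaluate_masks(pred_masks, gt_masks, aggregation: str = "per_image_mean"):
    """Metrics over a collection of mask pairs.

    Returns ``(report, per_image)`` where ``per_image`` is the list of
    individual :class:`MetricsReport` objects.  ``aggregation`` is either
    ``per_image_mean`` (average of per-image metrics, the default reporting
    mode) or ``pooled`` (confusion counts summed over the set first).
    """
    if len(pred_masks) != len(gt_masks) or len(pred_masks) == 0:
        raise ValidationError("need equal, non-zero numbers of predicted and reference masks")
    per_counts = [confusion_counts(p, g) for p, g in zip(pred_masks, gt_masks)]
    per_image = [compute_metrics(c) for c in per_counts]
    n = len(per_image)
    if aggregation == "per_image_mean":
        report = MetricsReport(
            dsc=float(np.mean([m.dsc for m in per_image])),
            iou=float(np.mean([m.iou for m in per_image])),
            precision=float(np.mean([m.precision for m in per_image])),
            sensitivity=float(np.mean([m.sensitivity for m in per_image])),
            n_images=n,
            aggregation=aggregation,
        )
    elif aggregation == "pooled":
        total = per_counts[0]
        for c in per_counts[1:]:
            total = total + c
        pooled = compute_metrics(total)
        report = MetricsReport(
            dsc=pooled.dsc, iou=pooled.iou, precision=pooled.precision,
            sensitivity=pooled.sensitivity, n_images=n, aggregation=aggregation,
        )
    else:
        raise ValidationError(f"unknown aggregation mode: {aggregation!r}")
    return report, per_image


def metrics_to_csv(per_image: list[MetricsReport], report: MetricsReport,
                   path: str | Path, image_ids: list[str] | None = None) -> pd.DataFrame:
    """Write one row per image plus an aggregate row."""
    ids = image_ids if image_ids is not None else [f"{i:05d}" for i in range(len(per_image))]
    rows = [
        {"image_id": i, "dsc": m.dsc, "iou": m.iou,
         "precision": m.precision, "sensitivity": m.sensitivity}
        for i, m in zip(ids, per_image)
    ]
    rows.append({
        "image_id": f"aggregate({report.aggregation})", "dsc": report.dsc,
        "iou": report.iou, "precision": report.precision,
        "sensitivity": report.sensitivity,
    })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
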