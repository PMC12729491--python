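"""Loss decomposition, confusion-count bookkeeping and metric algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waveseg.autograd import Tensor
from waveseg.errors import ValidationError
from waveseg.losses_metrics import (ConfusionCounts, LossConfig, bce_loss,
                                    compute_metrics, confusion_counts, dice_loss,
                                    evaluate_masks, hybrid_loss, metrics_to_csv)


class TestHybridLoss:
    def test_perfect_prediction_has_negligible_loss(self, rng):
        target = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        probs = np.clip(target, 1e-7, 1 - 1e-7)
        assert float(hybrid_loss(probs, target).data) < 1e-3

    def test_uniform_half_bce_is_log_two(self):
        target = np.array([[[[1.0, 0.0], [0.0, 1.0]]]])
        probs = np.full_like(target, 0.5)
        loss = hybrid_loss(probs, target, LossConfig(lambda_ce=1.0, lambda_dice=0.0))
        assert float(loss.data) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_decomposes_into_weighted_components(self, rng):
        target = (rng.random((3, 1, 6, 6)) > 0.6).astype(float)
        probs = rng.random((3, 1, 6, 6)) * 0.98 + 0.01
        total = float(hybrid_loss(probs, target).data)
        ce = float(bce_loss(probs, target).data)
        dc = float(dice_loss(probs, target).data)
        assert total == pytest.approx(0.4 * ce + 0.6 * dc, abs=1e-9)

    def test_loss_decreases_toward_target(self, rng):
        target = (rng.random((1, 1, 8, 8)) > 0.5).astype(float)
        start = rng.random((1, 1, 8, 8)) * 0.96 + 0.02
        goal = np.clip(target, 1e-4, 1 - 1e-4)
        values = []
        for alpha in np.linspace(0.0, 1.0, 10):
            probs = (1 - alpha) * start + alpha * goal
            values.append(float(hybrid_loss(probs, target).data))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_gradient_flows_through_loss(self, rng):
        target = (rng.random((1, 1, 4, 4)) > 0.5).astype(float)
        probs = Tensor(rng.random((1, 1, 4, 4)) * 0.9 + 0.05, requires_grad=True)
        hybrid_loss(probs, target).backward()
        assert probs.grad is not None and np.abs(probs.grad).max() > 0

    def test_invalid_inputs_rejected(self, rng):
        probs = rng.random((1, 1, 4, 4))
        with pytest.raises(ValidationError, match="binary"):
            hybrid_loss(probs, probs)  # non-binary target
        with pytest.raises(ValidationError, match="shape"):
            hybrid_loss(probs, np.zeros((1, 1, 2, 2)))
        with pytest.raises(ValidationError):
            LossConfig(lambda_ce=0.0, lambda_dice=0.0)


class TestConfusionCounts:
    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.random((16, 16)) > 0.5).astype(np.uint8)
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == int(m.sum())
        assert c.total == m.size

    def test_all_ones_versus_all_zeros(self):
        c = confusion_counts(np.ones((4, 4), dtype=np.uint8), np.zeros((4, 4), dtype=np.uint8))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 16, 0, 0)

    def test_matches_naive_pixel_loop(self, rng):
        for _ in range(200):
            pred = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
            gt = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
            c = confusion_counts(pred, gt)
            tp = fp = fn = tn = 0
            for i in range(16):
                for j in range(16):
                    p, g = pred[i, j], gt[i, j]
                    tp += p and g
                    fp += p and not g
                    fn += (not p) and g
                    tn += (not p) and (not g)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)

    def test_rejects_soft_predictions(self, rng):
        with pytest.raises(ValidationError, match="binary"):
            confusion_counts(rng.random((4, 4)), np.zeros((4, 4)))


class TestMetrics:
    def test_worked_example(self):
        m = compute_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=12))
        assert m.dsc == pytest.approx(2 / 3, abs=1e-4)
        assert m.iou == pytest.approx(0.5)
        assert m.precision == pytest.approx(2 / 3, abs=1e-4)
        assert m.sensitivity == pytest.approx(2 / 3, abs=1e-4)

    def test_perfect_and_degenerate_conventions(self):
        perfect = compute_metrics(ConfusionCounts(5, 0, 0, 11))
        assert (perfect.dsc, perfect.iou, perfect.precision, perfect.sensitivity) == (1, 1, 1, 1)
        both_empty = compute_metrics(ConfusionCounts(0, 0, 0, 16))
        assert (both_empty.dsc, both_empty.iou, both_empty.precision,
                both_empty.sensitivity) == (1, 1, 1, 1)
        missed = compute_metrics(ConfusionCounts(0, 0, 7, 9))
        assert (missed.dsc, missed.iou, missed.precision, missed.sensitivity) == (0, 0, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_dsc_iou_identity_and_ranges(self, tp, fp, fn):
        m = compute_metrics(ConfusionCounts(tp, fp, fn, 10))
        assert 0.0 <= m.iou <= m.dsc <= 1.0
        assert 0.0 <= m.precision <= 1.0 and 0.0 <= m.sensitivity <= 1.0
        assert m.dsc == pytest.approx(2 * m.iou / (1 + m.iou), abs=1e-12)

    def test_aggregation_modes_differ_under_imbalance(self):
        big_good = (np.ones((8, 8), dtype=np.uint8), np.ones((8, 8), dtype=np.uint8))
        small_bad = (np.zeros((8, 8), dtype=np.uint8), np.eye(8, dtype=np.uint8))
        preds, gts = zip(big_good, small_bad)
        per_image, _ = evaluate_masks(list(preds), list(gts), "per_image_mean")
        pooled, _ = evaluate_masks(list(preds), list(gts), "pooled")
        assert per_image.dsc == pytest.approx(0.5)
        assert pooled.dsc == pytest.approx(2 * 64 / (2 * 64 + 8))

    def test_csv_export_has_per_image_and_aggregate_rows(self, tmp_path):
        preds = [np.ones((4, 4), dtype=np.uint8)] * 3
        gts = [np.ones((4, 4), dtype=np.uint8)] * 3
        report, per_image = evaluate_masks(preds, gts)
        df = metrics_to_csv(per_image, report, tmp_path / "m.csv")
        assert len(df) == 4
        assert set(df.columns) == {"image_id", "dsc", "iou", "precision", "sensitivity"}
        assert df.iloc[-1]["image_id"].startswith("aggregate")
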