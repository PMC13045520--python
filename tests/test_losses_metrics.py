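"""Dice/DF losses and the Dice/Hausdorff evaluation metrics, cross-checked
against closed forms and the exhaustive brute-force oracle."""

import math

import numpy as np
import pytest

from prored.losses import df_loss, dice_loss, one_hot
from prored.masks import LabelMask
from prored.metrics import (EvalReport, dice_coefficient, hausdorff_bruteforce,
                            hausdorff_distance)
from prored.nn import Tensor
from prored.synthetic import generate_blob_masks

TWO = ("bg", "a")


def _probs_from_labels(labels, c):
    return Tensor(one_hot(labels, c))


class TestDiceLoss:
    def test_exact_onehot_prediction_is_near_zero(self):
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, 1:3, 1:3] = 1
        loss = dice_loss(_probs_from_labels(labels, 2), labels)
        assert float(loss.data) == pytest.approx(0.0, abs=1e-4)

    def test_complement_prediction_is_near_one(self):
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, :, :2] = 1
        wrong = 1 - labels
        loss = dice_loss(_probs_from_labels(wrong, 2), labels)
        assert float(loss.data) == pytest.approx(1.0, abs=1e-4)

    def test_uniform_probabilities_match_closed_form(self):
        # half-foreground toy: C=2, uniform p=1/2 everywhere.
        # dice_fg = (2·Σ p·g + ε)/(Σp + Σg + ε) = (2·(n/2)·0.5 + ε)/(n/2 + n/2·... )
        n = 16
        labels = np.zeros((1, 4, 4), dtype=int)
        labels[0, :2] = 1           # 8 foreground pixels
        probs = Tensor(np.full((1, 2, 4, 4), 0.5, np.float32))
        eps = 1e-5
        expected = 1 - (2 * 8 * 0.5 + eps) / (16 * 0.5 + 8 + eps)
        loss = dice_loss(probs, labels)
        assert float(loss.data) == pytest.approx(expected, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            dice_loss(Tensor(np.zeros((1, 2, 4, 4), np.float32)),
                      np.zeros((1, 5, 5), dtype=int))


class TestDFLoss:
    def test_perfect_prediction_zero(self):
        gt = np.random.default_rng(0).normal(size=(1, 2, 5, 5)).astype(np.float32)
        fg = np.ones((1, 5, 5), bool)
        assert float(df_loss(Tensor(gt), gt, fg).data) == 0.0

    def test_zero_prediction_against_unit_vectors_is_one(self):
        gt = np.zeros((1, 2, 4, 4), np.float32)
        gt[:, 0] = 0.6
        gt[:, 1] = 0.8  # unit norm everywhere
        fg = np.ones((1, 4, 4), bool)
        pred = Tensor(np.zeros_like(gt))
        assert float(df_loss(pred, gt, fg).data) == pytest.approx(1.0, abs=1e-6)

    def test_masked_to_foreground_and_empty_foreground(self):
        gt = np.ones((1, 2, 3, 3), np.float32)
        pred = Tensor(np.zeros_like(gt))
        fg = np.zeros((1, 3, 3), bool)
        assert float(df_loss(pred, gt, fg).data) == 0.0
        fg[0, 0, 0] = True
        assert float(df_loss(pred, gt, fg).data) == pytest.approx(2.0)


class TestDiceCoefficient:
    def test_examples(self):
        a = np.zeros((4, 4), dtype=int)
        a[:2, :2] = 1
        m = LabelMask(a, TWO)
        assert dice_coefficient(m, m, 1) == 1.0
        b = np.zeros((4, 4), dtype=int)
        b[2:, 2:] = 1
        assert dice_coefficient(m, LabelMask(b, TWO), 1) == 0.0
        # |A|=4, |B|=4, |A∩B|=2 → 0.5
        c = np.zeros((4, 4), dtype=int)
        c[0, :2] = 1
        c[1, 2:] = 1
        d = np.zeros((4, 4), dtype=int)
        d[0, :2] = 1
        d[2, :2] = 1
        assert dice_coefficient(LabelMask(c, TWO), LabelMask(d, TWO), 1) == 0.5

    def test_both_empty_defined_as_one_and_symmetry(self):
        empty = LabelMask(np.zeros((3, 3), dtype=int), TWO)
        assert dice_coefficient(empty, empty, 1) == 1.0
        for mask_a, mask_b in zip(generate_blob_masks(3, (16, 16), seed=0),
                                  generate_blob_masks(3, (16, 16), seed=1)):
            assert dice_coefficient(mask_a, mask_b, 1) == dice_coefficient(mask_b, mask_a, 1)


class TestHausdorff:
    def test_identical_masks_zero(self):
        m = generate_blob_masks(1, (16, 16), seed=2)[0]
        assert hausdorff_distance(m, m, 1) == 0.0

    def test_single_pixel_pair_is_euclidean(self):
        a = np.zeros((6, 6), dtype=int)
        a[0, 0] = 1
        b = np.zeros((6, 6), dtype=int)
        b[3, 4] = 1
        d = hausdorff_distance(LabelMask(a, TWO), LabelMask(b, TWO), 1)
        assert d == pytest.approx(5.0)

    def test_undefined_when_one_side_empty(self):
        a = np.zeros((4, 4), dtype=int)
        a[1, 1] = 1
        empty = LabelMask(np.zeros((4, 4), dtype=int), TWO)
        assert math.isnan(hausdorff_distance(LabelMask(a, TWO), empty, 1))

    def test_spacing_scales_distances(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 0] = 1
        b = np.zeros((4, 4), dtype=int)
        b[0, 3] = 1
        d = hausdorff_distance(LabelMask(a, TWO), LabelMask(b, TWO), 1, spacing=(2.0, 2.0))
        assert d == pytest.approx(6.0)

    def test_fast_path_matches_bruteforce_on_random_pairs(self):
        preds = generate_blob_masks(15, (32, 32), seed=5)
        gts = generate_blob_masks(15, (32, 32), seed=6)
        checked = 0
        for p, g in zip(preds, gts):
            for label in range(1, p.num_classes):
                fast = hausdorff_distance(p, g, label)
                slow = hausdorff_bruteforce(p, g, label)
                if math.isnan(fast):
                    assert math.isnan(slow)
                else:
                    assert fast == pytest.approx(slow, abs=1e-9)
                checked += 1
        assert checked >= 45


class TestEvalReport:
    def test_identity_masks_all_perfect(self):
        masks = generate_blob_masks(3, (16, 16), seed=7)
        report = EvalReport.from_masks(masks, masks)
        assert report.mean_dice == 1.0
        assert report.mean_hd == 0.0
        assert report.units == "px"

    def test_loss_metric_consistency_on_exact_prediction(self):
        # a prediction with Dice loss ≈ 0 also has dice_coefficient = 1
        labels = np.zeros((1, 6, 6), dtype=int)
        labels[0, 2:5, 1:4] = 1
        loss = dice_loss(_probs_from_labels(labels, 2), labels)
        m = LabelMask(labels[0], TWO)
        assert float(loss.data) < 1e-4 and dice_coefficient(m, m, 1) == 1.0

    def test_report_serialization(self, tmp_path):
        report = EvalReport({"a": 0.9, "b": 0.8}, {"a": 1.0, "b": float("nan")}, "px")
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        frame = report.to_frame()
        assert list(frame["class"]) == ["a", "b", "mean"]
        assert report.mean_hd == pytest.approx(1.0)  # NaN rows skipped

    def test_dice_bounds_enforced(self):
        with pytest.raises(ValueError):
            EvalReport({"a": 1.5}, {"a": 0.0})
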