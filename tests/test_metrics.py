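"""DSC, confusion-table metrics, tumor diameter and DSC summaries."""

import math

import numpy as np
import pytest

from rectalseg.core import StageCategory, StageLabel, StagePrediction, ValidationError
from rectalseg.losses import dice_loss
from rectalseg.metrics import (
    ConfusionTable2x2,
    accuracy,
    dsc,
    sensitivity,
    specificity,
    staging_confusion,
    summarize_dsc,
    tumor_diameter,
)


class TestDsc:
    def test_identical_masks(self, rng):
        m = rng.random((6, 6, 6)) > 0.5
        assert dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros_like(a)
        a[0, 0, 0] = True
        b[1, 1, 1] = True
        assert dsc(a, b) == 0.0

    def test_hand_counted_half_overlap(self):
        p = np.zeros((2, 2, 2), dtype=bool)
        g = np.zeros_like(p)
        p.ravel()[:4] = True
        g.ravel()[2:6] = True  # |P|=4, |G|=4, |P∩G|=2
        assert dsc(p, g) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = np.zeros((3, 3, 3), dtype=bool)
        assert dsc(z, z) == 1.0

    def test_symmetric(self, rng):
        a = rng.random((5, 5, 5)) > 0.4
        b = rng.random((5, 5, 5)) > 0.6
        assert dsc(a, b) == dsc(b, a)

    def test_complement_of_dice_loss_within_smoothing_bound(self, rng):
        for _ in range(25):
            p = rng.random((5, 5, 5)) > 0.5
            g = rng.random((5, 5, 5)) > 0.5
            s = int(p.sum()) + int(g.sum())
            if s == 0:
                continue
            gap = abs(dsc(p, g) - (1.0 - dice_loss(p.astype(float), g.astype(float))))
            assert gap <= 1.0 / (s + 1) + 1e-12
            # and exactly equal without smoothing
            assert dsc(p, g) == pytest.approx(
                1.0 - dice_loss(p.astype(float), g.astype(float), eps=0.0)
            )


class TestStagingMetrics:
    def test_published_contingency_pattern(self):
        t = ConfusionTable2x2(tp=92, fp=19, fn=27, tn=63)
        assert t.total == 201
        assert t.tp + t.fp == 111  # predicted >=T3 row
        assert t.fn + t.tn == 90  # predicted <=T2 row
        assert sensitivity(t) == pytest.approx(92 / 119, abs=5e-4)
        assert specificity(t) == pytest.approx(63 / 82, abs=5e-4)
        assert accuracy(t) == pytest.approx(155 / 201, abs=5e-4)

    def test_confusion_from_predictions(self):
        preds = [
            StagePrediction(StageCategory.GE_T3, 4),
            StagePrediction(StageCategory.LE_T2, 0),
            StagePrediction(StageCategory.LE_T2, 0, tumor_empty=True),
        ]
        truths = [StageLabel.t3(), StageLabel.t2(), StageLabel.t3()]
        t = staging_confusion(preds, truths)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 0, 1, 1)

    def test_all_correct(self):
        preds = [StagePrediction(StageCategory.GE_T3, 1)] * 5 + [
            StagePrediction(StageCategory.LE_T2, 0)
        ] * 5
        truths = [StageLabel.t3()] * 5 + [StageLabel.t2()] * 5
        t = staging_confusion(preds, truths)
        assert t.fp == t.fn == 0
        assert sensitivity(t) == specificity(t) == accuracy(t) == 1.0

    def test_undefined_sensitivity_is_nan(self):
        t = ConfusionTable2x2(tp=0, fp=2, fn=0, tn=3)
        assert math.isnan(sensitivity(t))
        assert specificity(t) == pytest.approx(0.6)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            staging_confusion([StagePrediction(StageCategory.LE_T2, 0)], [])

    def test_recount_matches_brute_force(self, rng):
        preds, truths = [], []
        for _ in range(60):
            p = bool(rng.integers(2))
            preds.append(
                StagePrediction(StageCategory.GE_T3 if p else StageCategory.LE_T2, int(p))
            )
            truths.append(StageLabel.t3() if rng.integers(2) else StageLabel.t2())
        t = staging_confusion(preds, truths)
        tp = sum(
            p.category is StageCategory.GE_T3 and g.category is StageCategory.GE_T3
            for p, g in zip(preds, truths)
        )
        pos = sum(g.category is StageCategory.GE_T3 for g in truths)
        assert sensitivity(t) == pytest.approx(tp / pos)
        correct = sum(p.category is g.category for p, g in zip(preds, truths))
        assert accuracy(t) == pytest.approx(correct / 60)


class TestTumorDiameter:
    def test_single_voxel(self):
        m = np.zeros((4, 4, 4), dtype=bool)
        m[1, 2, 3] = True
        assert tumor_diameter(m, (0.5, 0.5, 0.5)) == pytest.approx(0.5)

    def test_forty_voxel_rod_is_twenty_mm(self):
        m = np.zeros((50, 3, 3), dtype=bool)
        m[5:45, 1, 1] = True
        assert tumor_diameter(m, (0.5, 0.5, 0.5)) == pytest.approx(20.0)

    def test_sphere_diameter_within_one_voxel(self, rng):
        r = 5
        idx = np.indices((16, 16, 16)) - 8
        m = (idx**2).sum(axis=0) <= r * r
        d = tumor_diameter(m, (1.0, 1.0, 1.0))
        # brute-force maximum per-axis extent over all voxel pairs
        pts = np.argwhere(m)
        brute = max(
            (pts[:, a].max() - pts[:, a].min() + 1) for a in range(3)
        )
        assert d == pytest.approx(brute)
        assert abs(d - 2 * r) <= 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            tumor_diameter(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))


class TestSummarizeDsc:
    def test_median(self):
        s = summarize_dsc([0.2, 0.5, 0.8])
        assert s.median == pytest.approx(0.5)
        assert s.iqr[0] <= s.median <= s.iqr[1]

    def test_constant_list_zero_iqr(self):
        s = summarize_dsc([0.7] * 10)
        assert s.iqr == (pytest.approx(0.7), pytest.approx(0.7))

    def test_uniform_draws(self, rng):
        s = summarize_dsc(rng.random(100))
        assert s.median == pytest.approx(0.5, abs=0.15)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_dsc([])
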