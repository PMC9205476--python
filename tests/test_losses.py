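"""Dice loss, staging probability/loss and the combined objective."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rectalseg.core import ProbMaps, SegLabels, StageLabel, ValidationError
from rectalseg.losses import (
    LossConfig,
    combined_loss,
    combined_loss_grad,
    dice_loss,
    dice_loss_grad,
    staging_loss,
    staging_probability,
    staging_probability_argmax,
)


def _prob_maps(rng, shape=(4, 4, 4)):
    return ProbMaps.from_stack(rng.random((3, *shape)))


class TestDiceLoss:
    def test_hand_computed_example_without_smoothing(self):
        p = np.array([1.0, 1.0, 0.0, 0.0])
        g = np.array([0.0, 1.0, 1.0, 0.0])
        # 1 - 2*1/(2+2)
        assert dice_loss(p, g, eps=0.0) == pytest.approx(0.5)

    def test_perfect_overlap_is_zero(self, rng):
        g = (rng.random((5, 5, 5)) > 0.5).astype(float)
        assert dice_loss(g, g) == pytest.approx(0.0)

    def test_no_overlap_approaches_one(self, rng):
        g = np.ones((6, 6, 6))
        p = np.zeros_like(g)
        val = dice_loss(p, g)  # smoothed: S/(S+1) with S = |g|
        s = g.sum()
        assert val == pytest.approx(s / (s + 1))
        assert dice_loss(p, g, eps=0.0) == pytest.approx(1.0)

    def test_both_empty_defined_as_zero(self):
        z = np.zeros((3, 3, 3))
        assert dice_loss(z, z) == 0.0

    def test_gradient_matches_finite_differences(self, rng):
        p = rng.random(30)
        g = (rng.random(30) > 0.5).astype(float)
        grad = dice_loss_grad(p, g)
        eps = 1e-6
        for i in rng.choice(30, size=5, replace=False):
            p2 = p.copy()
            p2[i] += eps
            num = (dice_loss(p2, g) - dice_loss(p, g)) / eps
            assert grad[i] == pytest.approx(num, abs=1e-5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        p=arrays(np.float64, (27,), elements=st.floats(0, 1)),
        g=arrays(np.int8, (27,), elements=st.integers(0, 1)),
    )
    def test_bounded_and_permutation_invariant(self, p, g):
        val = dice_loss(p, g.astype(float))
        assert 0.0 <= val <= 1.0
        perm = np.random.RandomState(0).permutation(27)
        assert dice_loss(p[perm], g[perm].astype(float)) == pytest.approx(val)


class TestStagingProbability:
    def test_zero_tumor_channel(self, rng):
        maps = ProbMaps(
            tumor=np.zeros((3, 3, 3)),
            rectum=rng.random((3, 3, 3)),
            mesorectum=rng.random((3, 3, 3)),
        )
        assert staging_probability(maps) == 0.0

    def test_single_voxel_hand_value(self):
        t = np.zeros((2, 2, 2))
        r = np.zeros((2, 2, 2))
        t[1, 0, 1] = 0.9
        r[1, 0, 1] = 0.2
        maps = ProbMaps(tumor=t, rectum=r, mesorectum=np.zeros_like(t))
        assert staging_probability(maps) == pytest.approx(0.72)

    def test_tumor_fully_inside_rectum(self):
        ones = np.ones((3, 3, 3))
        maps = ProbMaps(tumor=ones, rectum=ones, mesorectum=ones)
        assert staging_probability(maps) == 0.0

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            maps = _prob_maps(rng)
            best = max(
                maps.tumor[i, j, k] * (1.0 - maps.rectum[i, j, k])
                for i in range(4)
                for j in range(4)
                for k in range(4)
            )
            assert staging_probability(maps) == pytest.approx(best)
            val, idx = staging_probability_argmax(maps.tumor, maps.rectum)
            assert val == pytest.approx(best)

    def test_permutation_invariant(self, rng):
        maps = _prob_maps(rng)
        flat = [m.ravel() for m in (maps.tumor, maps.rectum, maps.mesorectum)]
        perm = rng.permutation(flat[0].size)
        shuffled = ProbMaps.from_stack(
            np.stack([f[perm].reshape(maps.shape) for f in flat])
        )
        assert staging_probability(shuffled) == pytest.approx(staging_probability(maps))


class TestStagingLoss:
    @pytest.mark.parametrize(
        "g,p,expected",
        [(1, 1.0, -1.0), (-1, 0.0, -1.0), (-1, 1.0, 0.0), (1, 0.0, 0.0)],
    )
    def test_closed_form_values(self, g, p, expected):
        assert staging_loss(p, StageLabel.from_g(g)) == pytest.approx(expected)

    @pytest.mark.parametrize("g", [-1, 1])
    def test_slope_is_minus_g_exactly(self, g):
        label = StageLabel.from_g(g)
        # the loss is linear in p_staging, so a secant gives the exact slope
        slope = staging_loss(0.75, label) - staging_loss(0.25, label)
        assert slope / 0.5 == -g

    def test_range(self, rng):
        for _ in range(100):
            p = float(rng.random())
            for g in (-1, 1):
                assert -1.0 <= staging_loss(p, StageLabel.from_g(g)) <= 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            staging_loss(1.5, StageLabel.t3())


class TestCombinedLoss:
    def test_staging_only_case(self, rng):
        maps = ProbMaps(
            tumor=np.ones((2, 2, 2)),
            rectum=np.zeros((2, 2, 2)),
            mesorectum=np.zeros((2, 2, 2)),
        )  # p_staging = 1
        val = combined_loss(maps, None, StageLabel.t3(), LossConfig(lam=0.02))
        assert val == pytest.approx(-0.02)

    def test_lambda_zero_is_exactly_mean_dice(self, rng):
        maps = _prob_maps(rng)
        labels = SegLabels.from_stack(rng.random((3, 4, 4, 4)) > 0.5)
        cfg = LossConfig(lam=0.0)
        expected = np.mean(
            [
                dice_loss(maps.stack()[c], labels.stack()[c].astype(float))
                for c in range(3)
            ]
        )
        assert combined_loss(maps, labels, StageLabel.t2(), cfg) == expected

    def test_perfect_t2_prediction(self):
        t = np.zeros((4, 4, 4))
        t[1:3, 1:3, 1:3] = 1.0
        r = np.zeros((4, 4, 4))
        r[:3, :3, :3] = 1.0  # tumor strictly inside rectum
        m = np.zeros((4, 4, 4))
        m[3:, :, :] = 1.0
        maps = ProbMaps(tumor=t, rectum=r, mesorectum=m)
        labels = SegLabels(tumor=t > 0, rectum=r > 0, mesorectum=m > 0)
        val = combined_loss(maps, labels, StageLabel.t2(), LossConfig(lam=0.02))
        assert val == pytest.approx(0.0 + 0.02 * (-1.0))

    def test_grad_agrees_with_value(self, rng):
        stack = rng.random((3, 4, 4, 4))
        labels = SegLabels.from_stack(rng.random((3, 4, 4, 4)) > 0.5)
        cfg = LossConfig(lam=0.5)
        value, grad = combined_loss_grad(stack, labels, StageLabel.t3(), cfg)
        maps = ProbMaps.from_stack(stack)
        assert value == pytest.approx(combined_loss(maps, labels, StageLabel.t3(), cfg))
        assert grad.shape == stack.shape
        assert np.abs(grad).sum() > 0
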