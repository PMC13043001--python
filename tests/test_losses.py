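"""Closed-form and property tests of the segmentation losses."""

import math

import numpy as np
import pytest

from cryopick import nn
from cryopick.losses import (LossWeights, SemanticOutput, bce_loss, bce_loss_t,
                             dice_loss, dice_loss_t, focal_loss, focal_loss_t,
                             total_loss, total_loss_t)

W = LossWeights()


class TestBCE:
    def test_uniform_half_probability_gives_ln2(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        p = np.full_like(y, 0.5)
        assert bce_loss(p, y, W) == pytest.approx(math.log(2), abs=1e-9)

    def test_perfect_prediction_is_at_the_eps_floor(self):
        y = np.array([0.0, 1.0, 1.0])
        assert bce_loss(y, y, W) <= -math.log(1.0 - W.eps) + 1e-12

    def test_hand_computed_two_pixel_case(self):
        p, y = np.array([0.9, 0.2]), np.array([1.0, 0.0])
        expect = -(math.log(0.9) + math.log(0.8)) / 2
        assert bce_loss(p, y, W) == pytest.approx(expect, abs=1e-9)
        assert expect == pytest.approx(0.164252, abs=1e-6)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros(3), np.zeros(4), W)


class TestDice:
    def test_identical_binary_masks_vanish_with_smoothing(self):
        y = (np.arange(16) % 3 == 0).astype(float)
        assert dice_loss(y, y, W) < 1e-6

    def test_uniform_half_on_half_foreground_is_half(self):
        y = np.zeros(100)
        y[:50] = 1.0
        p = np.full(100, 0.5)
        assert dice_loss(p, y, W) == pytest.approx(0.5, abs=1e-6)

    def test_disjoint_supports_approach_one(self):
        p = np.array([1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert dice_loss(p, y, W) == pytest.approx(1.0, abs=1e-5)


class TestFocal:
    def test_reduces_to_bce_at_gamma0_alpha1(self, rng):
        w = LossWeights(alpha=1.0, gamma=0.0)
        for _ in range(100):
            n = int(rng.integers(1, 50))
            p = rng.random(n)
            y = (rng.random(n) > 0.5).astype(float)
            assert focal_loss(p, y, w) == pytest.approx(
                bce_loss(p, y, w), abs=1e-12
            )

    def test_confident_correct_limit_is_near_zero(self):
        y = np.ones(10)
        p = np.full(10, 1.0 - W.eps)
        assert focal_loss(p, y, W) < 1e-6

    def test_single_pixel_hand_computed(self):
        w = LossWeights(alpha=0.25, gamma=2.0)
        got = focal_loss(np.array([0.9]), np.array([1.0]), w)
        expect = 0.25 * 0.1**2 * (-math.log(0.9))
        assert got == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(2.6341e-4, rel=1e-4)


class TestTotal:
    def _mk_out(self, p, aux=None):
        return SemanticOutput(prob=p, aux_probs=aux if aux is not None else [])

    def test_mu_zero_recovers_backbone(self, rng):
        p = rng.random((8, 8))
        y = (rng.random((8, 8)) > 0.6).astype(float)
        w = LossWeights(mu=(0.0, 0.0, 0.0))
        total, _ = total_loss(self._mk_out(p), y, w)
        backbone = (
            w.lambda_bce * bce_loss(p, y, w)
            + w.lambda_dice * dice_loss(p, y, w)
            + w.lambda_focal * focal_loss(p, y, w)
        )
        assert total == pytest.approx(backbone, abs=1e-12)

    def test_closed_form_assembly_with_defaults(self):
        # main and aux heads all at p=0.5, half the pixels foreground
        y = np.zeros(100)
        y[:50] = 1.0
        p = np.full(100, 0.5)
        out = self._mk_out(p, aux=[p.copy() for _ in range(3)])
        total, breakdown = total_loss(out, y, W)
        ln2 = math.log(2)
        focal_half = 0.25 * 0.5**2 * ln2
        expect = 1 * ln2 + 1 * 0.5 + 0.5 * focal_half + 0.9 * (ln2 + 0.5)
        assert total == pytest.approx(expect, abs=1e-6)
        assert total == pytest.approx(2.288640, abs=1e-5)
        assert breakdown["main_bce"] == pytest.approx(ln2, abs=1e-9)

    def test_perfect_prediction_floor(self):
        y = (np.arange(64) % 2).astype(float)
        out = self._mk_out(y.copy(), aux=[y.copy() for _ in range(3)])
        total, _ = total_loss(out, y, W)
        assert total < 1e-5

    def test_aux_count_enforced(self):
        y = np.ones(4)
        out = self._mk_out(np.ones(4), aux=[np.ones(4)])
        with pytest.raises(ValueError):
            total_loss(out, y, W)

    def test_homogeneous_in_weights(self, rng):
        p = rng.random(64)
        y = (rng.random(64) > 0.5).astype(float)
        aux = [rng.random(64) for _ in range(3)]
        w1 = LossWeights()
        w2 = LossWeights(lambda_bce=2.0, lambda_dice=2.0, lambda_focal=1.0,
                         mu=(0.8, 0.6, 0.4))
        t1, _ = total_loss(SemanticOutput(p, aux), y, w1)
        t2, _ = total_loss(SemanticOutput(p, aux), y, w2)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)


class TestTensorParity:
    """The autodiff losses used in training match the numpy API."""

    def test_all_losses_agree(self, rng):
        p = rng.random((2, 1, 8, 8))
        y = (rng.random((2, 1, 8, 8)) > 0.5).astype(float)
        pt, yt = nn.Tensor(p), nn.Tensor(y)
        assert float(bce_loss_t(pt, yt, W).data) == pytest.approx(
            bce_loss(p, y, W), rel=1e-5
        )
        assert float(dice_loss_t(pt, yt, W).data) == pytest.approx(
            dice_loss(p, y, W), rel=1e-5
        )
        assert float(focal_loss_t(pt, yt, W).data) == pytest.approx(
            focal_loss(p, y, W), rel=1e-5
        )
        aux = [rng.random((2, 1, 8, 8)) for _ in range(3)]
        t_np, _ = total_loss(SemanticOutput(p, aux), y, W)
        t_t, _ = total_loss_t(pt, [nn.Tensor(a) for a in aux], yt, W)
        assert float(t_t.data) == pytest.approx(t_np, rel=1e-5)
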