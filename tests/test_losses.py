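"""Training objectives: closed forms, gradients, and invariances."""

import numpy as np
import pytest

from locseg3d import bce_dice_loss, bce_loss, dice_loss, multiclass_dice_loss
from locseg3d.nn import Tensor

from conftest import fd_gradcheck


def _mask(rng, shape=(4, 4, 4), p=0.4):
    return (rng.random(shape) < p).astype(np.float64)


class TestDiceLoss:
    def test_perfect_hard_prediction_printed_variant_scores_half(self, rng):
        y = _mask(rng)
        s = y.sum()
        loss = dice_loss(y, y, variant="printed")
        # exact closed form with smoothing s=1: 1 - (S+1)/(2S+1)
        assert abs(loss.value - (1 - (s + 1) / (2 * s + 1))) < 1e-6
        assert abs(loss.value - 0.5) < 1.0 / (2 * s)

    def test_perfect_prediction_factor2_variant_scores_zero(self, rng):
        y = _mask(rng)
        assert abs(dice_loss(y, y, variant="factor2").value) < 1e-9

    def test_disjoint_masks_score_one(self):
        y = np.zeros((4, 4, 4))
        y[:2] = 1
        p = np.zeros((4, 4, 4))
        p[2:] = 1
        for variant in ("printed", "factor2"):
            assert abs(dice_loss(y, p, variant=variant).value - 1.0) < 0.04

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_monotone_under_growing_overlap(self, rng):
        """Adding overlap voxels one at a time never increases the loss."""
        y = np.ones((4, 4, 4))
        p = np.zeros(64)
        prev = dice_loss(y, p.reshape(4, 4, 4)).value
        for i in range(64):
            p[i] = 1.0
            cur = dice_loss(y, p.reshape(4, 4, 4)).value
            assert cur <= prev + 1e-12
            prev = cur

    def test_permutation_invariance(self, rng):
        y, p = _mask(rng), rng.random((4, 4, 4))
        perm = rng.permutation(64)
        a = dice_loss(y, p).value
        b = dice_loss(y.ravel()[perm].reshape(4, 4, 4), p.ravel()[perm].reshape(4, 4, 4)).value
        assert abs(a - b) < 1e-12


class TestBceLoss:
    def test_uniform_half_prediction_gives_log_two(self, rng):
        y = _mask(rng)
        p = np.full((4, 4, 4), 0.5)
        assert abs(bce_loss(y, p).value - np.log(2.0)) < 1e-7

    def test_confident_correct_prediction(self):
        y = np.zeros((4, 4, 4))
        y[0] = 1.0
        p = np.where(y == 1, 0.999, 0.001)
        # per-voxel loss is -log(0.999) ~= 1.0005e-3 everywhere
        assert abs(bce_loss(y, p).value - (-np.log(0.999))) < 1e-9

    def test_perfect_prediction_clipping_floor(self):
        y = np.ones((2, 2, 2))
        loss = bce_loss(y, np.ones((2, 2, 2)), clip=1e-7)
        assert abs(loss.value - (-np.log(1 - 1e-7))) < 1e-12

    def test_nonnegative_and_zero_only_at_target(self, rng):
        y = _mask(rng)
        assert bce_loss(y, rng.random((4, 4, 4))).value > 0


class TestCombinedLoss:
    def test_value_is_sum_of_components(self, rng):
        y = _mask(rng)
        p = np.clip(rng.random((4, 4, 4)), 0.01, 0.99)
        lv = bce_dice_loss(y, p)
        assert abs(lv.value - (lv.components["dice"] + lv.components["bce"])) < 1e-6
        assert lv.value >= max(lv.components.values()) - 1e-12

    def test_gradient_matches_finite_differences(self, rng):
        y = Tensor(_mask(rng))
        p = Tensor(np.clip(rng.random((4, 4, 4)), 0.05, 0.95), requires_grad=True)
        assert fd_gradcheck(lambda: bce_dice_loss(y, p).tensor, [p]) < 1e-3

    def test_component_gradients_sum(self, rng):
        """Gradient of the combined loss equals the sum of the two parts."""
        y = _mask(rng)
        p = np.clip(rng.random((4, 4, 4)), 0.05, 0.95)
        tp = Tensor(p, requires_grad=True)
        bce_dice_loss(Tensor(y), tp).backward()
        g_sum = tp.grad.copy()
        tp.grad = None
        dice_loss(Tensor(y), tp).backward()
        g_d = tp.grad.copy()
        tp.grad = None
        bce_loss(Tensor(y), tp).backward()
        assert np.allclose(g_sum, g_d + tp.grad, atol=1e-10)


class TestMulticlassDice:
    def _onehot(self, labels, k):
        return np.stack([(labels == i).astype(np.float64) for i in range(k)])

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_perfect_hard_prediction_variants(self, rng, k):
        labels = rng.integers(0, k, (4, 4, 4))
        y = self._onehot(labels, k)
        printed = multiclass_dice_loss(y, y, variant="printed").value
        assert abs(printed - 0.5) < 0.05  # smoothing shifts each term slightly
        assert abs(multiclass_dice_loss(y, y, variant="factor2").value) < 1e-6

    def test_all_background_prediction_term_matches_hand_count(self):
        # 4^3 grid, half voxels class 0, half class 1; prediction puts
        # everything in the background class
        labels = np.zeros((4, 4, 4), dtype=int)
        labels[2:] = 1
        y = self._onehot(labels, 2)
        p = np.zeros_like(y)
        p[0] = 1.0
        n, s_bg = 64.0, 32.0
        lv = multiclass_dice_loss(y, p, variant="printed", smooth=0.0)
        expected_bg = s_bg / (s_bg + n)  # overlap 32 / (|y_bg| + |p_bg|)
        assert abs(lv.components["dice_class_0"] - expected_bg) < 1e-9
        assert abs(lv.components["dice_class_1"] - 0.0) < 1e-9
        assert abs(lv.value - (1 - 0.5 * expected_bg)) < 1e-9

    def test_non_simplex_prediction_rejected(self, rng):
        y = self._onehot(rng.integers(0, 3, (4, 4, 4)), 3)
        bad = np.full((3, 4, 4, 4), 0.5)
        with pytest.raises(ValueError, match="simplex"):
            multiclass_dice_loss(y, bad)

    def test_gradient_matches_finite_differences(self, rng):
        labels = rng.integers(0, 3, (4, 4, 4))
        y = Tensor(self._onehot(labels, 3))
        logits = Tensor(rng.normal(size=(3, 4, 4, 4)), requires_grad=True)

        def build():
            return multiclass_dice_loss(y, logits.softmax(0)).tensor

        assert fd_gradcheck(build, [logits]) < 1e-3
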