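"""Dice/cross-entropy losses, deep supervision, quality weighting."""

import math

import numpy as np
import pytest

import mscaseg as m
from mscaseg.losses import (
    LossConfig,
    cross_entropy_loss,
    data_quality_loss,
    dice_loss,
    segmentation_loss,
    total_loss,
)
from mscaseg.volume_io import one_hot_encode


def _random_probs(shape=(4, 4, 4, 4), seed=0):
    rng = np.random.default_rng(seed)
    p = rng.random(shape)
    return p / p.sum(axis=0, keepdims=True)


def _labels_with_all_classes(shape=(4, 4, 4), seed=1):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 4, shape)
    labels.flat[:4] = [0, 1, 2, 3]
    return labels


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        g = one_hot_encode(_labels_with_all_classes())
        assert dice_loss(g, g).item() < 1e-6

    def test_zero_overlap_is_one(self):
        labels = np.full((3, 3, 3), 2)
        g = one_hot_encode(labels)
        p = one_hot_encode(np.full((3, 3, 3), 1)).astype(float)
        assert dice_loss(p, g, class_set=(2,)).item() == pytest.approx(1.0, abs=1e-5)

    def test_two_voxel_toy_matches_hand_evaluation(self):
        """G = [(1,0),(0,1)], P = [(0.8,0.2),(0.4,0.6)]: direct formula."""
        G = np.array([[1.0, 0.0], [0.0, 1.0]])  # (K=2, 2 voxels)
        P = np.array([[0.8, 0.4], [0.2, 0.6]])
        # class 0: 2*0.8 / (0.8^2+0.4^2 + 1 + eps); class 1: 2*0.6 / (0.04+0.36 + 1 + eps)
        eps = 1e-5
        expected = 1 - 0.5 * (1.6 / (1.8 + eps) + 1.2 / (1.4 + eps))
        assert dice_loss(P, G, class_set=(0, 1)).item() == pytest.approx(expected, abs=1e-12)

    def test_empty_class_set_rejected(self):
        g = one_hot_encode(_labels_with_all_classes())
        with pytest.raises(ValueError):
            dice_loss(g, g, class_set=())

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros((4, 2, 2, 2)), np.zeros((4, 3, 3, 3)))

    def test_monotone_along_interpolation_to_truth(self):
        """Dice loss decreases as P moves linearly from uniform to one-hot G."""
        g = one_hot_encode(_labels_with_all_classes((6, 6, 6)))
        uniform = np.full_like(g, 0.25)
        values = [
            dice_loss((1 - t) * uniform + t * g, g).item()
            for t in np.linspace(0, 1, 11)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        labels = _labels_with_all_classes()
        p = one_hot_encode(labels).astype(float)
        assert cross_entropy_loss(p, labels).item() <= -math.log(1 - 1e-5) + 1e-9

    def test_uniform_prediction_is_ln4(self):
        labels = _labels_with_all_classes()
        p = np.full((4,) + labels.shape, 0.25)
        assert cross_entropy_loss(p, labels).item() == pytest.approx(math.log(4), abs=1e-6)

    def test_three_voxel_toy_matches_hand_computation(self):
        labels = np.array([1, 2, 0]).reshape(3, 1, 1)
        p = np.zeros((4, 3, 1, 1))
        p[:, 0] = np.array([0.1, 0.6, 0.2, 0.1]).reshape(4, 1, 1)
        p[:, 1] = np.array([0.2, 0.1, 0.5, 0.2]).reshape(4, 1, 1)
        p[:, 2] = np.array([0.7, 0.1, 0.1, 0.1]).reshape(4, 1, 1)
        # all three voxels included: mean of -log 0.6, -log 0.5, -log 0.7
        expected = -(math.log(0.6) + math.log(0.5) + math.log(0.7)) / 3
        assert cross_entropy_loss(p, labels).item() == pytest.approx(expected, rel=1e-9)

    def test_background_voxel_exclusion_flag(self):
        """With ce_exclude_background only tissue voxels enter the mean."""
        labels = np.array([1, 2, 0]).reshape(3, 1, 1)
        p = np.zeros((4, 3, 1, 1))
        p[:, 0] = np.array([0.1, 0.6, 0.2, 0.1]).reshape(4, 1, 1)
        p[:, 1] = np.array([0.2, 0.1, 0.5, 0.2]).reshape(4, 1, 1)
        p[:, 2] = np.array([0.7, 0.1, 0.1, 0.1]).reshape(4, 1, 1)
        cfg = LossConfig(ce_exclude_background=True)
        expected = -(math.log(0.6) + math.log(0.5)) / 2
        assert cross_entropy_loss(p, labels, cfg).item() == pytest.approx(expected, rel=1e-9)

    def test_all_excluded_warns_and_returns_zero(self):
        labels = np.zeros((2, 2, 2), dtype=int)
        p = np.full((4, 2, 2, 2), 0.25)
        with pytest.warns(UserWarning):
            value = cross_entropy_loss(p, labels, LossConfig(ce_exclude_background=True))
        assert value.item() == 0.0


class TestSegmentationLoss:
    def test_perfect_single_stage_near_zero(self):
        labels = _labels_with_all_classes()
        p = one_hot_encode(labels).astype(float)
        cfg = LossConfig(ds_weights=(1.0,))
        assert segmentation_loss([p], labels, cfg).item() < 1e-4

    def test_weighted_linearity(self):
        """Two identical stages at (0.25, 0.5) equal 3x the stage at 0.25."""
        labels = _labels_with_all_classes()
        p = _random_probs(seed=3)
        single = segmentation_loss([p], labels, LossConfig(ds_weights=(0.25,))).item()
        double = segmentation_loss([p, p], labels, LossConfig(ds_weights=(0.25, 0.5))).item()
        assert double == pytest.approx(3 * single, rel=1e-9)

    def test_low_resolution_stage_upsampled(self):
        labels = _labels_with_all_classes((8, 8, 8))
        low = _random_probs((4, 4, 4, 4), seed=4)
        full = _random_probs((4, 8, 8, 8), seed=5)
        cfg = LossConfig(ds_weights=(0.25, 0.5))
        value = segmentation_loss([low, full], labels, cfg).item()
        assert np.isfinite(value) and value > 0

    def test_stage_count_mismatch_rejected(self):
        labels = _labels_with_all_classes()
        p = _random_probs()
        with pytest.raises(ValueError):
            segmentation_loss([p], labels, LossConfig(ds_weights=(0.25, 0.5)))

    def test_default_weights_are_the_ascending_five(self):
        assert LossConfig().ds_weights == (0.03125, 0.0625, 0.125, 0.25, 0.5)


class TestDataQualityAndTotal:
    def test_zero_weight_annihilates(self):
        labels = _labels_with_all_classes()
        assert data_quality_loss(_random_probs(), labels, 0.0).item() == 0.0

    def test_unit_weight_equals_cross_entropy(self):
        labels = _labels_with_all_classes()
        p = _random_probs(seed=6)
        assert data_quality_loss(p, labels, 1.0).item() == pytest.approx(
            cross_entropy_loss(p, labels).item(), rel=1e-12
        )

    def test_half_weight_scales_closed_form(self):
        labels = _labels_with_all_classes()
        p = np.full((4,) + labels.shape, 0.25)
        assert data_quality_loss(p, labels, 0.5).item() == pytest.approx(
            0.5 * math.log(4), abs=1e-6
        )

    def test_out_of_range_weight_rejected(self):
        with pytest.raises(ValueError):
            data_quality_loss(_random_probs(), _labels_with_all_classes(), 1.5)

    def test_lambda_zero_reduces_to_segmentation_loss(self):
        labels = _labels_with_all_classes()
        stages = [_random_probs(seed=s) for s in range(5)]
        cfg = LossConfig(lambda_=0.0)
        tot, bd = total_loss(stages, labels, 0.7, cfg)
        assert tot.item() == pytest.approx(segmentation_loss(stages, labels, cfg).item())
        assert bd["data"] == 0.0

    def test_additivity_of_components(self):
        labels = _labels_with_all_classes()
        stages = [_random_probs(seed=s) for s in range(5)]
        cfg = LossConfig(lambda_=1.0)
        tot, bd = total_loss(stages, labels, 0.6, cfg)
        assert abs(tot.item() - (bd["seg"] + cfg.lambda_ * bd["data"])) < 1e-12

    def test_losses_finite_and_nonnegative_on_extreme_inputs(self):
        labels = _labels_with_all_classes()
        hard = one_hot_encode((_labels_with_all_classes(seed=9) + 1) % 4).astype(float)
        stages = [hard] * 5
        tot, _ = total_loss(stages, labels, 1.0, LossConfig())
        assert np.isfinite(tot.item()) and tot.item() >= 0


def test_total_loss_gradient_matches_finite_differences():
    """Analytic gradient w.r.t. logits agrees with central differences."""
    from mscaseg import grad
    from mscaseg.grad import Parameter, Tensor

    rng = np.random.default_rng(0)
    labels = _labels_with_all_classes((4, 4, 4))
    logits = rng.standard_normal((4, 4, 4, 4))
    cfg = LossConfig(ds_weights=(0.25, 0.5), lambda_=1.0)
    low = _random_probs((4, 2, 2, 2), seed=2)

    def loss_of(arr):
        t = Parameter(arr) if isinstance(arr, np.ndarray) else arr
        p = grad.softmax(t, axis=0)
        tot, _ = total_loss([Tensor(low), p], labels, 0.8, cfg)
        return t, tot

    t, tot = loss_of(logits.copy())
    tot.backward()
    h = 1e-5
    idx_list = [tuple(rng.integers(0, 4, 4)) for _ in range(12)]
    for idx in idx_list:
        up, dn = logits.copy(), logits.copy()
        up[idx] += h
        dn[idx] -= h
        _, lu = loss_of(up)
        _, ld = loss_of(dn)
        numeric = (lu.item() - ld.item()) / (2 * h)
        assert numeric == pytest.approx(float(t.grad[idx]), rel=1e-4, abs=1e-8)
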