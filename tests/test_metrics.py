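"""Dice coefficient, HD95 against a brute-force oracle, paired tests."""

import math

import numpy as np
import pytest

import mscaseg as m
from mscaseg.metrics import (
    dice_coefficient,
    evaluate_segmentation,
    hd95,
    paired_test_bonferroni,
)


def _brute_force_hd95(A, B, spacing):
    """O(|A| * |B|) all-pairs oracle for the symmetric 95th-percentile HD."""
    pa = np.argwhere(A) * np.asarray(spacing)
    pb = np.argwhere(B) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    h_ab = np.percentile(d.min(axis=1), 95)
    h_ba = np.percentile(d.min(axis=0), 95)
    return max(h_ab, h_ba)


class TestDiceCoefficient:
    def test_identical_masks_100(self):
        a = np.random.default_rng(0).random((6, 6, 6)) < 0.4
        assert dice_coefficient(a, a) == 100.0

    def test_disjoint_masks_0(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert dice_coefficient(a, b) == 0.0

    def test_counting_example(self):
        """|A| = |B| = 8, |A & B| = 4 gives 50%."""
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a.flat[:8] = True
        b.flat[4:12] = True
        assert dice_coefficient(a, b) == pytest.approx(50.0)

    def test_both_empty_is_perfect_agreement(self):
        e = np.zeros((3, 3, 3), bool)
        assert dice_coefficient(e, e) == 100.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.random((5, 5, 5)) < 0.3
        b = rng.random((5, 5, 5)) < 0.3
        assert dice_coefficient(a, b) == dice_coefficient(b, a)


class TestHD95:
    def test_identical_masks_zero(self):
        a = np.random.default_rng(2).random((6, 6, 6)) < 0.4
        assert hd95(a, a) == 0.0

    def test_single_voxels_axis_distance(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 4, 4] = True
        b[5, 4, 4] = True
        assert hd95(a, b) == pytest.approx(3.0)

    def test_spacing_scales_distance(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[4, 2, 4] = True
        b[4, 6, 4] = True
        assert hd95(a, b, spacing=(1.0, 1.5, 1.0)) == pytest.approx(6.0)

    def test_empty_mask_undefined(self):
        a = np.zeros((4, 4, 4), bool)
        b = a.copy()
        b[1, 1, 1] = True
        assert math.isnan(hd95(a, b))
        assert math.isnan(hd95(b, a))

    def test_matches_brute_force_oracle_on_random_pairs(self):
        """Exact agreement with the all-pairs oracle on 50 random 12^3 pairs."""
        rng = np.random.default_rng(3)
        for trial in range(50):
            a = rng.random((12, 12, 12)) < 0.1
            b = rng.random((12, 12, 12)) < 0.1
            if not a.any() or not b.any():
                continue
            spacing = (1.0, 1.25, 0.8) if trial % 2 else (1.0, 1.0, 1.0)
            assert hd95(a, b, spacing) == pytest.approx(
                _brute_force_hd95(a, b, spacing), abs=1e-9
            ), f"trial {trial}"

    def test_monotone_as_mask_grows_toward_reference(self):
        """Adding A's voxels to B never increases hd95(A, B)."""
        rng = np.random.default_rng(4)
        a = rng.random((10, 10, 10)) < 0.2
        voxels = np.argwhere(a)
        b = np.zeros_like(a)
        b[tuple(voxels[0])] = True
        prev = math.inf
        for frac in (0.25, 0.5, 0.75, 1.0):
            k = max(1, int(frac * len(voxels)))
            b2 = np.zeros_like(a)
            b2[tuple(voxels[:k].T)] = True
            cur = hd95(a, b2)
            assert cur <= prev + 1e-9
            prev = cur


class TestEvaluateSegmentation:
    def test_identity_report(self, phantom_pair):
        _, labels = phantom_pair
        rep = evaluate_segmentation(labels, labels)
        assert all(v == 100.0 for v in rep.dice_pct.values())
        assert all(v == 0.0 for v in rep.hd95_mm.values())
        assert rep.macro_dice_pct == 100.0

    def test_missing_class_flagged_undefined(self):
        gt = np.zeros((8, 8, 8), dtype=np.int16)
        gt[2:6, 2:6, 2:6] = 2
        pred = gt.copy()
        pred[pred == 2] = 0  # GM relabelled to background
        rep = evaluate_segmentation(pred, gt)
        assert rep.dice_pct["GM"] == 0.0
        assert math.isnan(rep.hd95_mm["GM"])
        assert rep.n_hd95_undefined >= 1

    def test_report_is_composition_of_per_class_metrics(self, phantom_pair):
        """Report rows equal independent dice_coefficient/hd95 recomputation."""
        from mscaseg.phantom import CorruptionSpec, corrupt_labels

        _, labels = phantom_pair
        pred = corrupt_labels(
            labels, CorruptionSpec(mode="erode", severity=1, target_class=2), seed=0
        )
        rep = evaluate_segmentation(pred, labels, spacing=(1, 1, 1))
        for code, name in ((1, "CSF"), (2, "GM"), (3, "WM")):
            a, b = pred.data == code, labels.data == code
            assert rep.dice_pct[name] == pytest.approx(dice_coefficient(a, b))
            assert rep.hd95_mm[name] == pytest.approx(hd95(a, b, (1, 1, 1)))


class TestPairedTest:
    def test_identical_scores_null(self):
        res = paired_test_bonferroni([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 3)
        assert res.t == 0.0 and res.p == 1.0 and res.p_adjusted == 1.0
        assert res.degenerate

    def test_single_comparison_no_adjustment(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(10), rng.random(10)
        res = paired_test_bonferroni(a, b, 1)
        assert res.p_adjusted == pytest.approx(res.p)

    def test_adjustment_multiplies_and_caps(self):
        rng = np.random.default_rng(6)
        a, b = rng.random(10), rng.random(10)
        res = paired_test_bonferroni(a, b, 4)
        assert res.p_adjusted == pytest.approx(min(1.0, 4 * res.p))

    def test_closed_form_t_statistic(self):
        """Differences (1,2,3,4): t = mean / (sd / sqrt(n))."""
        b = np.zeros(4)
        a = np.array([1.0, 2.0, 3.0, 4.0])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / math.sqrt(4))
        res = paired_test_bonferroni(a, b, 1)
        assert res.t == pytest.approx(expected_t)
        assert not res.degenerate

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_test_bonferroni([1.0], [2.0], 1)


def test_dice_coefficient_complements_dice_loss():
    """1 - DC/100 equals the single-class Dice loss on one-hot masks."""
    rng = np.random.default_rng(7)
    a = rng.random((6, 6, 6)) < 0.4
    b = rng.random((6, 6, 6)) < 0.4
    dc = dice_coefficient(a, b) / 100.0
    loss = m.dice_loss(
        a[None].astype(float), b[None].astype(float), class_set=(0,)
    ).item()
    assert 1.0 - dc == pytest.approx(loss, abs=1e-5)
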