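"""Schedule, augmentation, folds, short training runs and inference."""

import numpy as np
import pytest

import mscaseg as m
from mscaseg.train import SGD, TrainConfig, augment, kfold_split, poly_lr
from mscaseg.volume_io import LabelMap, PatchPair, Volume


@pytest.fixture(scope="module")
def small_phantom():
    cfg = m.PhantomConfig(shape=(48, 48, 48))
    return m.generate_phantom(cfg, seed=21)


def _train_cfg(**kw):
    kw.setdefault("patch_size", 32)
    kw.setdefault("max_epoch", 2)
    kw.setdefault("iters_per_epoch", 2)
    kw.setdefault("batch_size", 1)
    return TrainConfig(**kw)


class TestPolyLR:
    def test_initial_value(self):
        assert poly_lr(0, TrainConfig()) == pytest.approx(0.01)

    def test_final_value_zero(self):
        cfg = TrainConfig()
        assert poly_lr(cfg.max_epoch, cfg) == 0.0

    def test_midpoint_closed_form(self):
        cfg = TrainConfig(max_epoch=500)
        assert poly_lr(250, cfg) == pytest.approx(0.01 * 0.5 ** 0.9, rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            poly_lr(501, TrainConfig(max_epoch=500))


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(0)
        return PatchPair(
            image_patch=rng.random((8, 8, 8)),
            label_patch=rng.integers(0, 4, (8, 8, 8)),
            origin=(0, 0, 0),
            size=(8, 8, 8),
        )

    def test_no_flags_identity(self):
        p = self._pair()
        out = augment(p, seed=1, flags=())
        np.testing.assert_array_equal(out.image_patch, p.image_patch)
        np.testing.assert_array_equal(out.label_patch, p.label_patch)

    def test_deterministic_under_seed(self):
        p = self._pair()
        a = augment(p, seed=3)
        b = augment(p, seed=3)
        np.testing.assert_array_equal(a.image_patch, b.image_patch)
        np.testing.assert_array_equal(a.label_patch, b.label_patch)

    def test_image_and_labels_transformed_identically(self):
        p = self._pair()
        marked = PatchPair(
            image_patch=p.label_patch.astype(float),
            label_patch=p.label_patch,
            origin=p.origin,
            size=p.size,
        )
        out = augment(marked, seed=11)
        np.testing.assert_array_equal(out.image_patch.astype(int), out.label_patch)

    def test_flip_is_involution(self):
        p = self._pair()
        once = np.flip(p.image_patch, axis=0)
        np.testing.assert_array_equal(np.flip(once, axis=0), p.image_patch)


class TestKFold:
    def test_partition_10_into_5(self):
        folds = kfold_split(10, 5, seed=0)
        assert len(folds) == 5
        val_union = np.sort(np.concatenate([v for _, v in folds]))
        np.testing.assert_array_equal(val_union, np.arange(10))
        assert all(len(v) == 2 for _, v in folds)
        for tr, va in folds:
            assert set(tr) & set(va) == set()

    def test_deterministic(self):
        a = kfold_split(12, 5, seed=4)
        b = kfold_split(12, 5, seed=4)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(va, vb)

    def test_uneven_sizes_differ_by_at_most_one(self):
        sizes = sorted(len(v) for _, v in kfold_split(11, 5, seed=0))
        assert sizes == [2, 2, 2, 2, 3]

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5)


class TestTraining:
    def test_empty_data_rejected(self, tiny_arch):
        with pytest.raises(ValueError):
            m.train([], _train_cfg(), tiny_arch)

    def test_lambda_zero_logs_zero_data_loss(self, small_phantom, tiny_arch):
        cfg = _train_cfg(lambda_=0.0, seed=1)
        _, log = m.train([small_phantom], cfg, tiny_arch)
        assert all(row["loss_data"] == 0.0 for row in log.iterations)

    def test_logged_lr_follows_poly_schedule(self, small_phantom, tiny_arch):
        cfg = _train_cfg(seed=2, max_epoch=3, iters_per_epoch=2)
        _, log = m.train([small_phantom], cfg, tiny_arch)
        for row in log.iterations:
            assert row["lr"] == poly_lr(row["epoch"], cfg)

    def test_same_seed_identical_trajectories(self, small_phantom, tiny_arch):
        cfg = _train_cfg(seed=5)
        _, log_a = m.train([small_phantom], cfg, tiny_arch)
        _, log_b = m.train([small_phantom], cfg, tiny_arch)
        la = [r["loss_total"] for r in log_a.iterations]
        lb = [r["loss_total"] for r in log_b.iterations]
        np.testing.assert_allclose(la, lb, atol=1e-6)

    def test_same_seed_identical_final_parameters(self, small_phantom, tiny_arch):
        cfg = _train_cfg(seed=6)
        net_a, _ = m.train([small_phantom], cfg, tiny_arch)
        net_b, _ = m.train([small_phantom], cfg, tiny_arch)
        for pa, pb in zip(net_a.parameters(), net_b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_log_rows_monotone_in_epoch_iteration(self, small_phantom, tiny_arch):
        cfg = _train_cfg(seed=7, max_epoch=2, iters_per_epoch=3)
        _, log = m.train([small_phantom], cfg, tiny_arch)
        keys = [(r["epoch"], r["iteration"]) for r in log.iterations]
        assert keys == sorted(keys)


class TestPredict:
    def test_single_window_equals_forward_argmax(self, tiny_net):
        rng = np.random.default_rng(0)
        vol = Volume(data=rng.random((32, 32, 32)))
        cfg = _train_cfg()
        pred = m.predict(tiny_net, vol, cfg)
        from mscaseg.train import _normalize_patch

        out = m.forward_pass(tiny_net, _normalize_patch(vol.data).astype(np.float32))
        np.testing.assert_array_equal(pred.data, out.outputs[-1].argmax(axis=0))

    def test_output_shape_matches_input(self, tiny_net, small_phantom):
        vol, _ = small_phantom
        pred = m.predict(tiny_net, vol, _train_cfg())
        assert pred.data.shape == vol.data.shape
        assert isinstance(pred, LabelMap)

    def test_requires_network(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError):
            m.predict(None, vol, _train_cfg())


def test_sgd_step_reduces_simple_quadratic():
    from mscaseg.grad import Parameter

    p = Parameter(np.array([4.0, -2.0]))
    opt = SGD([p], momentum=0.9, weight_decay=0.0)
    for _ in range(50):
        opt.zero_grad()
        (0.5 * (p * p).sum()).backward()
        opt.step(0.05)
    assert np.abs(p.data).max() < 0.1
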