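"""Training loop, schedule, augmentation, cross-validation and inference.

The optimizer follows the reference recipe: SGD with momentum 0.99 and
weight decay 3e-5, initial learning rate 0.01 decayed per epoch with the
poly schedule ``lr0 * (1 - epoch/max_epoch)^0.9``.  Each iteration samples a
foreground-biased patch pair, scores its label quality from Canny edge
overlap, applies axial flip/right-angle rotation augmentation, and descends
the total (deep-supervised + quality-weighted) loss.  Whole-volume inference
tiles the volume with 50%-overlapping windows blended by a Gaussian
importance map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .arch import ArchConfig, Network, build_network
from .edges import CannyParams, patch_quality
from .grad import Tensor
from .losses import LossConfig, total_loss
from .metrics import evaluate_segmentation
from .volume_io import LabelMap, PatchPair, Volume, sample_patch


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    max_epoch: int = 500
    iters_per_epoch: int = 250
    momentum: float = 0.99
    weight_decay: float = 3e-5
    patch_size: int = 128
    batch_size: int = 2
    lambda_: float = 1.0
    seed: int = 0
    augment: tuple[str, ...] = ("axial_flip", "rotation")
    folds: int = 5
    fg_bias: float = 1.0 / 3.0
    patience: int = 30
    val_interval: int = 1
    max_iterations: int | None = None  # truncate the schedule after N steps

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must lie in [0, 1)")
        if self.patch_size % 32:
            raise ValueError("patch_size must be divisible by 32")
        self.augment = tuple(self.augment)
        bad = set(self.augment) - {"axial_flip", "rotation"}
        if bad:
            raise ValueError(f"unknown augmentation flags: {sorted(bad)}")


@dataclass
class TrainingLog:
    """Per-iteration loss rows and per-epoch validation rows."""

    iterations: list[dict] = field(default_factory=list)
    epochs: list[dict] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.iterations)

    def save_jsonl(self, path) -> None:
        import json

        with open(path, "w") as fh:
            for row in self.iterations:
                fh.write(json.dumps({"kind": "iteration", **row}) + "\n")
            for row in self.epochs:
                fh.write(json.dumps({"kind": "epoch", **row}) + "\n")


def poly_lr(epoch_id: int, cfg: TrainConfig) -> float:
    """Polynomial decay: lr0 * (1 - epoch/max_epoch)^0.9, stepped per epoch."""
    if not 0 <= epoch_id <= cfg.max_epoch:
        raise ValueError(f"epoch_id {epoch_id} outside [0, {cfg.max_epoch}]")
    return cfg.initial_lr * (1.0 - epoch_id / cfg.max_epoch) ** 0.9


def augment(pair: PatchPair, seed: int | np.random.Generator = 0,
            flags=("axial_flip", "rotation")) -> PatchPair:
    """Seeded axial flip and right-angle in-plane rotation.

    Each enabled transform fires with probability 0.5; image and label
    patches are transformed identically.  Rotations are right angles about
    the axial axis so labels never need interpolation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img, lab = pair.image_patch, pair.label_patch
    if "axial_flip" in flags and rng.random() < 0.5:
        ax = int(rng.integers(2))  # an in-plane axis; axis 2 is axial
        img = np.flip(img, axis=ax)
        lab = np.flip(lab, axis=ax)
    if "rotation" in flags and rng.random() < 0.5:
        k = int(rng.integers(1, 4))
        img = np.rot90(img, k, axes=(0, 1))
        lab = np.rot90(lab, k, axes=(0, 1))
    return PatchPair(
        image_patch=np.ascontiguousarray(img),
        label_patch=np.ascontiguousarray(lab),
        origin=pair.origin,
        size=pair.size,
    )


def kfold_split(n_items: int, k: int = 5, seed: int = 0):
    """Deterministic shuffled k-fold partition of range(n_items)."""
    if k < 2 or k > n_items:
        raise ValueError(f"need 2 <= k <= n_items, got k={k}, n={n_items}")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed % (2 ** 31))
    return [(tr.copy(), va.copy()) for tr, va in kf.split(np.arange(n_items))]


class SGD:
    """SGD with (by default Nesterov) momentum and L2 weight decay."""

    def __init__(
        self,
        params,
        momentum: float = 0.99,
        weight_decay: float = 3e-5,
        nesterov: bool = True,
    ):
        self.params = list(params)
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            g = (p.grad if p.grad is not None else 0.0) + self.weight_decay * p.data
            v *= self.momentum
            v -= lr * g
            if self.nesterov:
                p.data += self.momentum * v - lr * g
            else:
                p.data += v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _normalize_patch(patch: np.ndarray) -> np.ndarray:
    """Z-scoring of an array; the intensity scale is arbitrary in MRI."""
    mu = patch.mean()
    sd = patch.std()
    return (patch - mu) / (sd if sd > 1e-8 else 1.0)


def _normalize_volume(vol: Volume) -> Volume:
    """Per-volume z-score, applied once so tissue intensities stay
    comparable across every patch sampled from the volume."""
    return Volume(
        data=_normalize_patch(vol.data.astype(np.float64)),
        spacing=vol.spacing,
        affine=vol.affine,
    )


def train(
    data: list[tuple[Volume, LabelMap]],
    cfg: TrainConfig,
    arch: ArchConfig,
    val_data: list[tuple[Volume, LabelMap]] | None = None,
    canny: CannyParams | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[Network, TrainingLog]:
    """Train a network on (volume, label) pairs; reproducible under cfg.seed.

    Each iteration assembles a batch of foreground-biased patches, computes
    the edge-overlap quality weight on the raw (pre-augmentation) patches,
    augments, and takes one SGD step on the total loss.  If ``val_data`` is
    given, whole-volume validation Dice is computed every ``val_interval``
    epochs and training stops early after ``patience`` epochs without
    improvement.
    """
    if not data:
        raise ValueError("training data must be non-empty")
    canny = canny or CannyParams()
    if loss_cfg is None:
        loss_cfg = LossConfig(
            ds_weights=arch.deep_supervision_weights, lambda_=cfg.lambda_
        )
    rng = np.random.default_rng(cfg.seed)
    net = build_network(arch, seed=cfg.seed)
    opt = SGD(net.parameters(), cfg.momentum, cfg.weight_decay)
    log = TrainingLog()
    best_dice, best_epoch = -np.inf, -1
    # normalize once per volume; quality weights are scale-invariant so the
    # normalized intensities serve edge extraction too
    data = [(_normalize_volume(v), l) for v, l in data]

    total_iters = 0
    for epoch in range(cfg.max_epoch):
        lr = poly_lr(epoch, cfg)
        for it in range(cfg.iters_per_epoch):
            if cfg.max_iterations is not None and total_iters >= cfg.max_iterations:
                return net, log
            total_iters += 1
            images, labels, weights = [], [], []
            for _ in range(cfg.batch_size):
                vol, lab = data[int(rng.integers(len(data)))]
                pair = sample_patch(
                    vol, lab, cfg.patch_size, seed=rng, fg_bias=cfg.fg_bias
                )
                w = patch_quality(pair.image_patch, pair.label_patch, canny)
                pair = augment(pair, seed=rng, flags=cfg.augment)
                images.append(pair.image_patch.astype(np.float64))
                labels.append(pair.label_patch)
                weights.append(w)
            x = Tensor(np.stack(images).astype(np.float32)[..., None])
            probs = net.forward(x)
            loss = Tensor(0.0)
            seg_sum = data_sum = 0.0
            for b in range(cfg.batch_size):
                stages_b = [p[b] for p in probs]
                lb, bd = total_loss(stages_b, labels[b], weights[b], loss_cfg)
                loss = loss + lb
                seg_sum += bd["seg"]
                data_sum += bd["data"]
            loss = loss * (1.0 / cfg.batch_size)
            opt.zero_grad()
            loss.backward()
            opt.step(lr)
            log.iterations.append(
                {
                    "epoch": epoch,
                    "iteration": it,
                    "lr": lr,
                    "loss_seg": seg_sum / cfg.batch_size,
                    "loss_data": data_sum / cfg.batch_size,
                    "loss_total": loss.item(),
                    "mean_w_data": float(np.mean(weights)),
                }
            )
        if val_data and (epoch % cfg.val_interval == 0 or epoch == cfg.max_epoch - 1):
            dices = []
            per_class: dict[str, list[float]] = {}
            for vol, lab in val_data:
                pred = predict(net, vol, cfg)
                rep = evaluate_segmentation(pred, lab, spacing=lab.spacing)
                dices.append(rep.macro_dice_pct)
                for name, d in rep.dice_pct.items():
                    per_class.setdefault(name, []).append(d)
            mean_dice = float(np.mean(dices))
            log.epochs.append(
                {
                    "epoch": epoch,
                    "val_macro_dice_pct": mean_dice,
                    **{f"val_dice_{k}": float(np.mean(v)) for k, v in per_class.items()},
                }
            )
            if mean_dice > best_dice:
                best_dice, best_epoch = mean_dice, epoch
            elif epoch - best_epoch >= cfg.patience:
                break
    return net, log


def _tile_starts(extent: int, window: int, step: int) -> list[int]:
    if extent <= window:
        return [0]
    starts = list(range(0, extent - window, step))
    starts.append(extent - window)
    return sorted(set(starts))


def _gaussian_window(size: int) -> np.ndarray:
    c = (size - 1) / 2.0
    x = np.arange(size) - c
    g1 = np.exp(-0.5 * (x / (size / 8.0)) ** 2)
    g = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    return g / g.max()


def predict(net: Network, vol: Volume, cfg: TrainConfig) -> LabelMap:
    """Sliding-window whole-volume segmentation.

    Windows of ``cfg.patch_size`` with 50% overlap are blended with a
    Gaussian importance map; the volume is zero-padded up to the window size
    if needed and the prediction cropped back.
    """
    if not isinstance(net, Network):
        raise ValueError("predict requires a built Network")
    w = cfg.patch_size
    step = w // 2
    shape = vol.data.shape
    vol = _normalize_volume(vol)
    padded_shape = tuple(max(s, w) for s in shape)
    data = np.zeros(padded_shape)
    data[tuple(slice(0, s) for s in shape)] = vol.data
    n_classes = net.cfg.n_classes
    acc = np.zeros((n_classes,) + padded_shape)
    wsum = np.zeros(padded_shape)
    gwin = _gaussian_window(w)
    for sx in _tile_starts(padded_shape[0], w, step):
        for sy in _tile_starts(padded_shape[1], w, step):
            for sz in _tile_starts(padded_shape[2], w, step):
                sl = (slice(sx, sx + w), slice(sy, sy + w), slice(sz, sz + w))
                window = data[sl].astype(np.float32)
                probs = net.forward(Tensor(window[None, ..., None]))[-1].data[0]
                acc[(slice(None),) + sl] += probs * gwin[None]
                wsum[sl] += gwin
    acc /= np.maximum(wsum, 1e-12)[None]
    labels = acc.argmax(axis=0).astype(np.int16)
    labels = labels[tuple(slice(0, s) for s in shape)]
    return LabelMap(data=labels, spacing=vol.spacing, affine=vol.affine)
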