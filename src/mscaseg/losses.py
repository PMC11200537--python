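"""Segmentation losses: Dice, cross-entropy, deep supervision, quality loss.

Probability maps are (K, D, H, W) with K=4 channels in the fixed class order
(background, CSF, GM, WM); label maps are integer (D, H, W) grids.  All loss
functions accept either plain numpy arrays or autodiff :class:`~mscaseg.grad.Tensor`
inputs and return a Tensor, so the same code path serves evaluation and
training.

Conventions (see docs/methods.md): the squared-sum Dice denominator; the
cross-entropy in the standard orientation -sum G log P; deep-supervision
stage weights applied to the compound (Dice + cross-entropy) per-stage loss;
background voxels excluded from both the Dice class average and the
cross-entropy voxel average; the quality-weighted cross-entropy applied at
the full-resolution head only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import grad
from .grad import Tensor, as_tensor
from .volume_io import LabelMap, N_CLASSES, one_hot_encode

#: Deep-supervision weights, ascending with resolution (1/16 ... full).
DEFAULT_DS_WEIGHTS = (0.03125, 0.0625, 0.125, 0.25, 0.5)

FOREGROUND_CLASSES = (1, 2, 3)


@dataclass
class LossConfig:
    """Deep-supervision weights, quality-loss trade-off and class handling.

    ``exclude_background`` removes the background channel from the Dice
    class average (tissue classes only).  ``ce_exclude_background``
    additionally restricts the cross-entropy mean to voxels whose ground
    truth is a tissue class; it defaults to off because a background class
    with no loss signal at all is never learned (see docs/methods.md).
    """

    ds_weights: tuple[float, ...] = DEFAULT_DS_WEIGHTS
    lambda_: float = 1.0
    exclude_background: bool = True
    ce_exclude_background: bool = False
    epsilon: float = 1e-5

    def __post_init__(self):
        self.ds_weights = tuple(float(w) for w in self.ds_weights)
        if any(w <= 0 for w in self.ds_weights):
            raise ValueError("all deep-supervision weights must be positive")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _labels_array(G) -> np.ndarray:
    data = G.data if isinstance(G, LabelMap) else np.asarray(G)
    return data.astype(np.int64)


def dice_loss(P, G_onehot, class_set=FOREGROUND_CLASSES, epsilon: float = 1e-5) -> Tensor:
    """Soft Dice loss averaged over ``class_set``.

    ``1 - (1/|S|) sum_k 2 sum P_k G_k / (sum P_k^2 + sum G_k^2 + eps)``.
    """
    P = as_tensor(P)
    G_onehot = as_tensor(G_onehot)
    if P.shape != G_onehot.shape:
        raise ValueError(f"shape mismatch: {P.shape} vs {G_onehot.shape}")
    class_set = tuple(class_set)
    if not class_set:
        raise ValueError("class_set must be non-empty")
    spatial = tuple(range(1, P.ndim))
    inter = (P * G_onehot).sum(axis=spatial)  # per-class overlap, (K,)
    psq = (P * P).sum(axis=spatial)
    gsq = (G_onehot * G_onehot).sum(axis=spatial)
    total = Tensor(0.0)
    for k in class_set:
        total = total + inter[k] / (psq[k] + gsq[k] + epsilon)
    return 1.0 - (2.0 / len(class_set)) * total


def cross_entropy_loss(P, G, cfg: LossConfig | None = None) -> Tensor:
    """Mean voxel-wise cross-entropy -log P_{G(i)}(i) over included voxels.

    With ``cfg.ce_exclude_background`` the mean runs only over voxels whose
    ground truth is a tissue class; predictions are clamped to
    [epsilon, 1] before the log.
    """
    cfg = cfg or LossConfig()
    P = as_tensor(P)
    labels = _labels_array(G)
    if P.shape[1:] != labels.shape:
        raise ValueError(f"shape mismatch: {P.shape[1:]} vs {labels.shape}")
    dtype = P.data.dtype
    if cfg.ce_exclude_background:
        include = (labels != 0).astype(dtype)
    else:
        include = np.ones_like(labels, dtype=dtype)
    n = include.sum()
    if n == 0:
        warnings.warn("cross_entropy_loss: all voxels excluded; returning 0")
        return Tensor(0.0)
    p_true = grad.select_class(P, labels)  # per-voxel P at the true class
    logp = grad.log(grad.clip(p_true, cfg.epsilon, 1.0))
    return -(logp * Tensor(include)).sum() * (1.0 / n)


def _upsample_prob(P: Tensor, out_spatial) -> Tensor:
    """Trilinear upsampling of a (K, d, h, w) map plus per-voxel renorm."""
    if tuple(P.shape[1:]) == tuple(out_spatial):
        return P
    k = P.shape[0]
    cl = grad.transpose(P, (1, 2, 3, 0)).reshape((1,) + tuple(P.shape[1:]) + (k,))
    up = grad.upsample_linear(cl, out_spatial)
    up = grad.transpose(up.reshape(tuple(up.shape[1:])), (3, 0, 1, 2))
    return up / up.sum(axis=0, keepdims=True)


def segmentation_loss(stages, G, cfg: LossConfig | None = None) -> Tensor:
    """Deep-supervised compound loss: sum_s w_s (Dice_s + CE_s).

    ``stages`` is an ascending-resolution sequence of probability maps (a
    :class:`~mscaseg.arch.StageOutputs` or a plain list); each map is
    upsampled to the ground-truth grid before the per-stage loss.
    """
    cfg = cfg or LossConfig()
    outputs = getattr(stages, "outputs", stages)
    if len(outputs) != len(cfg.ds_weights):
        raise ValueError(
            f"{len(outputs)} stage outputs but {len(cfg.ds_weights)} ds_weights"
        )
    labels = _labels_array(G)
    onehot = one_hot_encode(labels, N_CLASSES).astype(as_tensor(outputs[0]).data.dtype)
    class_set = FOREGROUND_CLASSES if cfg.exclude_background else tuple(range(N_CLASSES))
    total = Tensor(0.0)
    for w, P_s in zip(cfg.ds_weights, outputs):
        P_up = _upsample_prob(as_tensor(P_s), labels.shape)
        stage = dice_loss(P_up, onehot, class_set, cfg.epsilon) + cross_entropy_loss(
            P_up, labels, cfg
        )
        total = total + w * stage
    return total


def data_quality_loss(P, G, w_data: float, cfg: LossConfig | None = None) -> Tensor:
    """Quality-weighted cross-entropy at the full-resolution head."""
    if not 0.0 <= w_data <= 1.0:
        raise ValueError(f"w_data must lie in [0, 1], got {w_data}")
    return w_data * cross_entropy_loss(P, G, cfg)


def total_loss(stages, G, w_data: float, cfg: LossConfig | None = None):
    """L_total = L_seg + lambda * L_data; returns (Tensor, breakdown dict)."""
    cfg = cfg or LossConfig()
    outputs = getattr(stages, "outputs", stages)
    l_seg = segmentation_loss(stages, G, cfg)
    if cfg.lambda_ > 0:
        l_data = data_quality_loss(as_tensor(outputs[-1]), G, w_data, cfg)
    else:
        l_data = Tensor(0.0)
    total = l_seg + cfg.lambda_ * l_data
    breakdown = {
        "seg": l_seg.item(),
        "data": l_data.item(),
        "total": total.item(),
        "w_data": float(w_data),
    }
    return total, breakdown
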