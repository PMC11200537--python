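"""Evaluation metrics: per-class Dice (%), HD95 (mm), paired comparisons.

The Dice coefficient is reported as a percentage; HD95 is the 95th
percentile of directed voxel-center distances, symmetrized by the maximum of
both directions and measured in physical millimetres using the voxel
spacing.  Model comparisons use paired t-tests with Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage, stats

from .volume_io import CLASS_NAMES, LabelMap

TISSUE_CODES = {1: "CSF", 2: "GM", 3: "WM"}


def dice_coefficient(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap of two binary masks as a percentage in [0, 100].

    Two empty masks agree perfectly on absence and score 100.
    """
    A = np.asarray(A).astype(bool)
    B = np.asarray(B).astype(bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    na, nb = int(A.sum()), int(B.sum())
    if na + nb == 0:
        return 100.0
    return 200.0 * int((A & B).sum()) / (na + nb)


def _directed_h95(P: np.ndarray, G: np.ndarray, spacing) -> float:
    """95th percentile over p in P of the distance to the nearest g in G."""
    dt = ndimage.distance_transform_edt(~G, sampling=spacing)
    return float(np.percentile(dt[P], 95.0))


def hd95(A: np.ndarray, B: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile Hausdorff distance in mm.

    Computed on the voxel-center point sets of the full masks; the percentile
    interpolates linearly between order statistics.  Returns NaN (undefined)
    when either mask is empty.
    """
    A = np.asarray(A).astype(bool)
    B = np.asarray(B).astype(bool)
    if A.shape != B.shape:
        raise ValueError(f"mask shapes differ: {A.shape} vs {B.shape}")
    spacing = tuple(float(s) for s in np.broadcast_to(spacing, A.ndim))
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    if not A.any() or not B.any():
        return math.nan
    return max(_directed_h95(A, B, spacing), _directed_h95(B, A, spacing))


@dataclass
class ClassReport:
    """Per-tissue Dice (%) and HD95 (mm) plus macro averages.

    ``hd95_mm`` entries are NaN when undefined (an empty mask on either
    side); such classes are excluded from ``macro_hd95_mm`` and counted in
    ``n_hd95_undefined``.
    """

    dice_pct: dict[str, float] = field(default_factory=dict)
    hd95_mm: dict[str, float] = field(default_factory=dict)
    macro_dice_pct: float = math.nan
    macro_hd95_mm: float = math.nan
    n_hd95_undefined: int = 0

    def to_dict(self) -> dict:
        return {
            "dice_pct": dict(self.dice_pct),
            "hd95_mm": dict(self.hd95_mm),
            "macro_dice_pct": self.macro_dice_pct,
            "macro_hd95_mm": self.macro_hd95_mm,
            "n_hd95_undefined": self.n_hd95_undefined,
        }

    def to_rows(self) -> list[dict]:
        rows = [
            {"class": name, "dice_pct": self.dice_pct[name], "hd95_mm": self.hd95_mm[name]}
            for name in self.dice_pct
        ]
        rows.append(
            {"class": "macro", "dice_pct": self.macro_dice_pct, "hd95_mm": self.macro_hd95_mm}
        )
        return rows


def evaluate_segmentation(pred, gt, spacing=None) -> ClassReport:
    """Per-class Dice/HD95 report for a predicted vs ground-truth label map."""
    pred_data = pred.data if isinstance(pred, LabelMap) else np.asarray(pred)
    gt_data = gt.data if isinstance(gt, LabelMap) else np.asarray(gt)
    if pred_data.shape != gt_data.shape:
        raise ValueError(f"shapes differ: {pred_data.shape} vs {gt_data.shape}")
    if spacing is None:
        spacing = getattr(gt, "spacing", (1.0, 1.0, 1.0))
    report = ClassReport()
    hd_values = []
    for code, name in TISSUE_CODES.items():
        a = pred_data == code
        b = gt_data == code
        report.dice_pct[name] = dice_coefficient(a, b)
        h = hd95(a, b, spacing)
        report.hd95_mm[name] = h
        if math.isnan(h):
            report.n_hd95_undefined += 1
        else:
            hd_values.append(h)
    report.macro_dice_pct = float(np.mean(list(report.dice_pct.values())))
    report.macro_hd95_mm = float(np.mean(hd_values)) if hd_values else math.nan
    return report


class PairedTestResult(NamedTuple):
    t: float
    p: float
    p_adjusted: float
    degenerate: bool


def paired_test_bonferroni(scores_a, scores_b, n_comparisons: int = 1) -> PairedTestResult:
    """Two-sided paired t-test with Bonferroni-adjusted p value.

    Zero-variance differences are degenerate: all-zero differences give
    (t=0, p=1); constant nonzero differences give (t=+/-inf, p=0).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    if a.ndim != 1 or len(a) < 2:
        raise ValueError("need at least two paired observations")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    diff = a - b
    if np.ptp(diff) == 0:
        if diff[0] == 0:
            return PairedTestResult(0.0, 1.0, 1.0, True)
        t = math.copysign(math.inf, diff[0])
        return PairedTestResult(t, 0.0, 0.0, True)
    res = stats.ttest_rel(a, b)
    p_adj = min(1.0, n_comparisons * float(res.pvalue))
    return PairedTestResult(float(res.statistic), float(res.pvalue), p_adj, False)
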