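"""Canny edge extraction and the edge-overlap label-quality weight.

The quality weight is the Dice overlap between Canny edges of an intensity
patch and Canny edges of its label patch: well-annotated patches have tissue
boundaries that coincide with image gradients, so their edge maps overlap;
sloppy labels do not.  The weight multiplies the cross-entropy term of the
data-quality loss during training.

Edges are extracted slice-wise along the axial axis with the classical 2D
Canny operator (Gaussian smoothing, Sobel gradients, non-maximum suppression,
hysteresis).  Hysteresis thresholds are specified as fractions of each
slice's maximum smoothed-gradient magnitude, which makes the edge map exactly
invariant to affine rescaling of the intensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature

from .volume_io import N_CLASSES


@dataclass
class CannyParams:
    """Smoothing scale (voxels) and relative hysteresis thresholds."""

    sigma: float = 1.0
    low_frac: float = 0.1
    high_frac: float = 0.2

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.low_frac < self.high_frac <= 1.0:
            raise ValueError("need 0 < low_frac < high_frac <= 1")


def _slice_max_gradient(sl: np.ndarray, sigma: float) -> float:
    sm = ndimage.gaussian_filter(sl.astype(np.float64), sigma, mode="nearest")
    return float(np.hypot(ndimage.sobel(sm, 0), ndimage.sobel(sm, 1)).max())


def canny_edges(patch: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Slice-wise 2D Canny edges of a 3D patch, stacked along the axial axis.

    Returns a binary uint8 array of the patch's shape.  A constant patch (or
    slice) yields no edges.
    """
    params = params or CannyParams()
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 3:
        raise ValueError(f"expected a rank-3 patch, got rank {patch.ndim}")
    if patch.shape[0] < 3 or patch.shape[1] < 3:
        raise ValueError(f"in-plane extents must be >= 3, got {patch.shape[:2]}")
    out = np.zeros(patch.shape, dtype=np.uint8)
    for z in range(patch.shape[2]):
        sl = patch[:, :, z]
        gmax = _slice_max_gradient(sl, params.sigma)
        if gmax == 0.0:
            continue
        out[:, :, z] = feature.canny(
            sl,
            sigma=params.sigma,
            low_threshold=params.low_frac * gmax,
            high_threshold=params.high_frac * gmax,
        )
    return out


def edges_of_labels(label_patch: np.ndarray, params: CannyParams | None = None) -> np.ndarray:
    """Canny edges of a label patch, treating class codes as a scalar image."""
    label_patch = np.asarray(label_patch)
    if label_patch.size and (label_patch.min() < 0 or label_patch.max() >= N_CLASSES):
        raise ValueError(f"label codes must lie in 0..{N_CLASSES - 1}")
    return canny_edges(label_patch.astype(np.float64), params)


def quality_weight(edges_image: np.ndarray, edges_labels: np.ndarray) -> float:
    """Dice overlap of two binary edge maps, the label-quality score W.

    Both maps empty returns 1 (a featureless patch carries no evidence of
    label error); exactly one empty returns 0 (gross mismatch).
    """
    ei = np.asarray(edges_image).astype(bool)
    el = np.asarray(edges_labels).astype(bool)
    if ei.shape != el.shape:
        raise ValueError(f"edge map shapes differ: {ei.shape} vs {el.shape}")
    ni, nl = int(ei.sum()), int(el.sum())
    if ni == 0 and nl == 0:
        return 1.0
    if ni == 0 or nl == 0:
        return 0.0
    return 2.0 * int((ei & el).sum()) / (ni + nl)


def patch_quality(image_patch: np.ndarray, label_patch: np.ndarray,
                  params: CannyParams | None = None) -> float:
    """Convenience: W computed directly from an image/label patch pair."""
    return quality_weight(
        canny_edges(image_patch, params), edges_of_labels(label_patch, params)
    )
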