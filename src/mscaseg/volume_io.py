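"""NIfTI volume/label I/O, one-hot encoding and training-patch sampling.

Class codes follow the FSL FAST convention: 0 = background, 1 = CSF,
2 = gray matter, 3 = white matter.  Volumes are reoriented to the closest
RAS-canonical axis order on load, so axis 2 is treated as the axial
(inferior–superior) axis by the augmentation code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

N_CLASSES = 4
CLASS_NAMES = ("background", "CSF", "GM", "WM")


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and voxel-to-world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume requires a rank-3 array, got rank {self.data.ndim}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap(Volume):
    """Integer tissue labels over {0..3}, aligned to a :class:`Volume`."""

    def __post_init__(self):
        super().__post_init__()
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = self.data.astype(np.int16)
        if self.data.size and (self.data.min() < 0 or self.data.max() >= N_CLASSES):
            raise ValueError(f"label codes must lie in 0..{N_CLASSES - 1}")


@dataclass
class PatchPair:
    """Aligned image/label crops plus their origin in the source volume."""

    image_patch: np.ndarray
    label_patch: np.ndarray
    origin: tuple[int, int, int]
    size: tuple[int, int, int]


def read_volume(path, as_labels: bool = False) -> Volume:
    """Load a 3D NIfTI file, reoriented to the closest canonical (RAS) axes.

    Parameters
    ----------
    path : path-like
        A ``.nii`` or ``.nii.gz`` file with exactly 3 spatial dimensions.
    as_labels : bool
        Return a :class:`LabelMap` (integer tissue codes) instead of a
        :class:`Volume`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(
            f"expected a 3-dimensional image, got rank {img.ndim} from {path}"
        )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    cls = LabelMap if as_labels else Volume
    if as_labels:
        data = np.asarray(data).astype(np.int16)
    return cls(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: Volume, path) -> None:
    """Write a Volume/LabelMap as NIfTI-1; labels get an integer on-disk type."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelMap):
        data = vol.data.astype(np.int16)
    else:
        data = vol.data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def one_hot_encode(
    labels: LabelMap | np.ndarray, n_classes: int = N_CLASSES, dtype=np.float64
) -> np.ndarray:
    """One-hot encode integer labels into a (K, D, H, W) probability array."""
    data = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
    if data.size and data.max() >= n_classes:
        raise ValueError(
            f"label value {int(data.max())} out of range for K={n_classes}"
        )
    codes = np.arange(n_classes).reshape((n_classes,) + (1,) * data.ndim)
    return (data[None] == codes).astype(dtype)


def sample_patch(
    vol: Volume,
    labels: LabelMap,
    size,
    seed: int | np.random.Generator = 0,
    fg_bias: float = 0.0,
) -> PatchPair:
    """Sample an aligned image/label patch, optionally foreground-biased.

    With probability ``fg_bias`` the patch is centred on a uniformly drawn
    non-background voxel (origin clamped to bounds); otherwise the origin is
    uniform over the valid origin lattice.  Extents are half-open
    ``[origin, origin + size)``.
    """
    size = tuple(int(s) for s in np.broadcast_to(size, 3))
    shape = vol.data.shape
    if labels.data.shape != shape:
        raise ValueError("volume and label shapes differ")
    if any(sz > sh for sz, sh in zip(size, shape)):
        raise ValueError(f"patch size {size} exceeds volume shape {shape}")
    if not 0.0 <= fg_bias <= 1.0:
        raise ValueError("fg_bias must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    max_origin = [sh - sz for sh, sz in zip(shape, size)]
    fg = None
    if fg_bias > 0 and rng.random() < fg_bias:
        fg = np.argwhere(labels.data != 0)
    if fg is not None and len(fg):
        center = fg[rng.integers(len(fg))]
        origin = tuple(
            int(np.clip(c - sz // 2, 0, mo))
            for c, sz, mo in zip(center, size, max_origin)
        )
    else:
        origin = tuple(int(rng.integers(mo + 1)) for mo in max_origin)
    sl = tuple(slice(o, o + sz) for o, sz in zip(origin, size))
    return PatchPair(
        image_patch=np.ascontiguousarray(vol.data[sl]),
        label_patch=np.ascontiguousarray(labels.data[sl]),
        origin=origin,
        size=size,
    )
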