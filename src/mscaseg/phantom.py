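"""Synthetic brain-like phantoms with exact labels and controlled corruption.

The phantom emulates a skull-stripped, bias-corrected T1-weighted volume:
three nested ellipsoidal tissue compartments (CSF shell, gray-matter shell,
white-matter core) with class-specific Gaussian intensity variation, an
optional smooth multiplicative bias field parameterized as exp(polynomial)
over normalized coordinates, and additive Gaussian or Rician noise.  Label
corruption (erosion, dilation, boundary jitter, class swap) produces the
"inaccurate annotation" regimes that the edge-overlap quality weight is
designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, N_CLASSES, Volume

# Monomial exponents -> coefficient, over coordinates normalized to [-1, 1].
BiasCoeffs = dict[tuple[int, int, int], float]

DEFAULT_CLASS_MEANS = (0.0, 40.0, 90.0, 140.0)  # background, CSF, GM, WM
DEFAULT_CLASS_SDS = (0.0, 6.0, 8.0, 8.0)


def _as_triple(x) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(x, dtype=float), 3)
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class PhantomConfig:
    """Geometry, intensity and degradation parameters of a phantom.

    ``shell_radii`` are (outer CSF, middle GM, inner WM) ellipsoid semi-axes
    as fractions of the volume shape; scalars mean isotropic fractions.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    shell_radii: tuple = (0.45, 0.35, 0.25)
    class_means: tuple[float, ...] = DEFAULT_CLASS_MEANS
    class_sds: tuple[float, ...] = DEFAULT_CLASS_SDS
    bias_coeffs: BiasCoeffs = field(default_factory=dict)
    noise_sd: float = 4.0
    noise_model: str = "gaussian"

    def __post_init__(self):
        self.shape = tuple(int(s) for s in np.broadcast_to(self.shape, 3))
        self.shell_radii = tuple(_as_triple(r) for r in self.shell_radii)
        if len(self.shell_radii) != 3:
            raise ValueError("shell_radii needs outer, middle and inner semi-axes")
        outer, middle, inner = self.shell_radii
        for a_out, a_in in zip(outer, middle):
            if a_out <= a_in:
                raise ValueError("shells must be strictly nested (outer > middle)")
        for a_out, a_in in zip(middle, inner):
            if a_out <= a_in:
                raise ValueError("shells must be strictly nested (middle > inner)")
        self.class_means = tuple(float(v) for v in self.class_means)
        self.class_sds = tuple(float(v) for v in self.class_sds)
        if any(sd < 0 for sd in self.class_sds):
            raise ValueError("class_sds must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model: {self.noise_model!r}")


@dataclass
class CorruptionSpec:
    """A label-corruption recipe: what to do, how hard, and to which class."""

    mode: str = "erode"
    severity: int = 1
    target_class: int | str = "all"

    def __post_init__(self):
        if self.mode not in ("erode", "dilate", "boundary_jitter", "class_swap"):
            raise ValueError(f"unknown corruption mode: {self.mode!r}")
        if self.severity < 0:
            raise ValueError("severity must be non-negative")


def _normalized_grids(shape):
    return np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape],
        indexing="ij",
    )


def _poly_field(shape, coeffs: BiasCoeffs) -> np.ndarray:
    xs = _normalized_grids(shape)
    out = np.zeros(shape, dtype=np.float64)
    for expo, c in coeffs.items():
        if sum(expo) > 3:
            raise ValueError("bias polynomial order must be <= 3")
        term = np.full(shape, float(c))
        for ax, p in enumerate(expo):
            if p:
                term = term * xs[ax] ** p
        out += term
    return out


def apply_bias_field(vol: Volume, bias_coeffs: BiasCoeffs) -> Volume:
    """Multiply a volume by exp(polynomial) over normalized coordinates."""
    fieldmap = np.exp(_poly_field(vol.data.shape, bias_coeffs))
    return Volume(data=vol.data * fieldmap, spacing=vol.spacing, affine=vol.affine)


def _ellipsoid_mask(shape, semi_axes_frac) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [f * n for f, n in zip(semi_axes_frac, shape)]
    idx = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(idx, center, semi))
    return q <= 1.0


def generate_phantom(cfg: PhantomConfig, seed: int = 0) -> tuple[Volume, LabelMap]:
    """Build a phantom volume and its exact tissue label map.

    The label map is background outside the outer ellipsoid, CSF between the
    outer and middle shells, GM between middle and inner, WM inside the inner
    core.  Voxel intensity is ``bias(v) * noisy(mean[class] + sd[class]*z)``.
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(cfg.shape, dtype=np.int16)
    outer, middle, inner = cfg.shell_radii
    labels[_ellipsoid_mask(cfg.shape, outer)] = 1
    labels[_ellipsoid_mask(cfg.shape, middle)] = 2
    labels[_ellipsoid_mask(cfg.shape, inner)] = 3

    means = np.asarray(cfg.class_means, dtype=float)[labels]
    sds = np.asarray(cfg.class_sds, dtype=float)[labels]
    signal = means + sds * rng.standard_normal(cfg.shape)
    if cfg.noise_sd > 0 or cfg.noise_model == "rician":
        if cfg.noise_model == "gaussian":
            signal = signal + cfg.noise_sd * rng.standard_normal(cfg.shape)
        else:  # magnitude of signal + complex Gaussian noise
            re = signal + cfg.noise_sd * rng.standard_normal(cfg.shape)
            im = cfg.noise_sd * rng.standard_normal(cfg.shape)
            signal = np.hypot(re, im)
    intensity = signal * np.exp(_poly_field(cfg.shape, cfg.bias_coeffs))
    return (
        Volume(data=intensity),
        LabelMap(data=labels),
    )


def _target_classes(spec: CorruptionSpec):
    if spec.target_class == "all":
        return (1, 2, 3)
    return (int(spec.target_class),)


def _relabel_to_nearest(labels: np.ndarray, removed: np.ndarray, cls: int) -> None:
    """Give removed voxels the label of the nearest non-``cls`` voxel."""
    inside = labels == cls
    _, idx = ndimage.distance_transform_edt(inside, return_indices=True)
    labels[removed] = labels[tuple(i[removed] for i in idx)]


def corrupt_labels(labels: LabelMap, spec: CorruptionSpec, seed: int = 0) -> LabelMap:
    """Apply a deterministic, seeded corruption to a label map.

    severity 0 is the identity for every mode.  ``erode``/``dilate`` use a
    ball structuring element of radius ``severity``; ``boundary_jitter``
    relabels each boundary voxel to a uniformly drawn neighboring class with
    probability ``min(1, 0.25 * severity)``; ``class_swap`` (severity >= 1)
    cyclically relabels the target tissue class to the next tissue code.
    With ``target_class='all'``, morphology applies to tissue classes 1..3 in
    ascending order on the evolving map.
    """
    out = labels.data.copy()
    if spec.severity == 0:
        return LabelMap(data=out, spacing=labels.spacing, affine=labels.affine)
    rng = np.random.default_rng(seed)

    if spec.mode in ("erode", "dilate"):
        ball = _ball(spec.severity)
        for cls in _target_classes(spec):
            mask = out == cls
            if not mask.any():
                continue
            if spec.mode == "erode":
                shrunk = ndimage.binary_erosion(mask, structure=ball)
                removed = mask & ~shrunk
                _relabel_to_nearest(out, removed, cls)
            else:
                grown = ndimage.binary_dilation(mask, structure=ball)
                out[grown & ~mask] = cls
    elif spec.mode == "boundary_jitter":
        out = _boundary_jitter(out, spec, rng)
    else:  # class_swap
        for cls in _target_classes(spec):
            nxt = cls % 3 + 1
            out[labels.data == cls] = nxt
    return LabelMap(data=out, spacing=labels.spacing, affine=labels.affine)


def _ball(radius: int) -> np.ndarray:
    z, y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1, -radius : radius + 1]
    return (x * x + y * y + z * z) <= radius * radius


_NEIGHBOR_SHIFTS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


def _neighbor_stack(labels: np.ndarray) -> np.ndarray:
    """(6, ...) array of 6-neighbor labels, edge-replicated at the border."""
    padded = np.pad(labels, 1, mode="edge")
    core = tuple(slice(1, -1) for _ in range(3))
    stack = []
    for shift in _NEIGHBOR_SHIFTS:
        sl = tuple(slice(1 + s, labels.shape[a] + 1 + s) for a, s in enumerate(shift))
        stack.append(padded[sl])
    return np.stack(stack)


def boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one 6-neighbor of a different class."""
    data = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
    return (_neighbor_stack(data) != data[None]).any(axis=0)


def _boundary_jitter(out: np.ndarray, spec: CorruptionSpec, rng) -> np.ndarray:
    p = min(1.0, 0.25 * spec.severity)
    neighbors = _neighbor_stack(out)
    boundary = (neighbors != out[None]).any(axis=0)
    # One uniform draw per voxel: severities nest, so the changed set grows
    # monotonically with severity under a fixed seed.
    u_change = rng.random(out.shape)
    u_pick = rng.random(out.shape)
    change = boundary & (u_change < p)
    if not change.any():
        return out
    nb = neighbors[:, change]  # (6, M)
    own = out[change]
    valid = nb != own[None]
    counts = valid.sum(axis=0)
    pick = np.minimum((u_pick[change] * counts).astype(int), counts - 1)
    # choose the pick-th valid neighbor per voxel
    order = np.cumsum(valid, axis=0) - 1
    sel = (order == pick[None]) & valid
    out = out.copy()
    out[change] = nb[sel.argmax(axis=0), np.arange(nb.shape[1])]
    return out


def analytic_class_volumes(cfg: PhantomConfig) -> dict[int, float]:
    """Closed-form ellipsoid-shell volumes (voxels) for each tissue class."""
    vols = []
    for frac in cfg.shell_radii:
        a, b, c = (f * n for f, n in zip(frac, cfg.shape))
        vols.append(4.0 / 3.0 * np.pi * a * b * c)
    outer, middle, inner = vols
    return {1: outer - middle, 2: middle - inner, 3: inner}
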