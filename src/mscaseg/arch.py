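"""Five-stage 3D encoder-decoder with multiscale convolutional attention.

The network is a U-shaped fully convolutional segmenter over 4 tissue
classes.  A full-resolution stem feeds five encoder stages with downsampling
rates 2, 4, 8, 16 and 32; the two shallow stages use plain 3x3x3
convolution blocks, the three deep stages (the deepest acting as the
bottleneck) use multiscale convolutional attention (MSCA) blocks.  The
decoder mirrors the encoder per resolution, upsampling with strided
deconvolution and concatenating same-resolution encoder features; every
decoder resolution carries a supervision head projecting to the class
probabilities, giving five deep-supervision outputs in ascending resolution.
Instance normalization (learnable scale/shift) is used throughout.

The 3D MSCA attention op computes ``Conv1x1x1( sum_i Sca_i( ConvD(X) ) ) * X``
where ConvD is a 5x5x5 depth-wise aggregation, Sca_0 is the identity, and
Sca_1..3 are triples of sequential depth-wise strip convolutions
(k x 1 x 1, 1 x k x 1, 1 x 1 x k) with extents 5, 7 and 11, approximating
large-kernel convolutions at strip cost.  The product with the input is
elementwise: the projected multiscale context acts as attention weights.

Internally feature maps are channels-last, (N, D, H, W, C); the public
probability maps are channels-first (K, D, H, W) to match the label
conventions of the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import grad
from .grad import Parameter, Tensor, as_tensor
from .volume_io import N_CLASSES

DEFAULT_STAGE_CHANNELS = (32, 64, 128, 256, 320)
TINY_STAGE_CHANNELS = (8, 16, 32, 64, 64)

PARAM_DTYPE = np.float32


@dataclass
class MSCAParams:
    """Configuration of one MSCA attention op."""

    channels: int
    dw_kernel: int = 5
    branch_kernels: tuple[int, ...] = (5, 7, 11)
    include_identity_branch: bool = True

    def __post_init__(self):
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        for k in (self.dw_kernel, *self.branch_kernels):
            if k < 3 or k % 2 == 0:
                raise ValueError(f"kernel extents must be odd and >= 3, got {k}")


@dataclass
class ArchConfig:
    """Network hyperparameters.

    ``stage_block_type`` defaults to plain convolution for stages 1-2 and
    MSCA for stages 3-5; setting ``use_msca=False`` (the attention ablation)
    substitutes plain convolution everywhere.
    """

    n_stages: int = 5
    stage_channels: tuple[int, ...] = DEFAULT_STAGE_CHANNELS
    stage_block_type: tuple[str, ...] | None = None
    n_classes: int = N_CLASSES
    deep_supervision_weights: tuple[float, ...] = (0.03125, 0.0625, 0.125, 0.25, 0.5)
    use_msca: bool = True
    branch_kernels: tuple[int, ...] = (5, 7, 11)
    dw_kernel: int = 5
    in_channels: int = 1
    norm_eps: float = 1e-5

    def __post_init__(self):
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        if len(self.stage_channels) != self.n_stages:
            raise ValueError("stage_channels length must equal n_stages")
        if self.stage_block_type is None:
            if self.use_msca:
                self.stage_block_type = tuple(
                    "conv" if i < 2 else "msca" for i in range(self.n_stages)
                )
            else:
                self.stage_block_type = ("conv",) * self.n_stages
        self.stage_block_type = tuple(self.stage_block_type)
        if len(self.stage_block_type) != self.n_stages:
            raise ValueError("stage_block_type length must equal n_stages")
        if any(t not in ("conv", "msca") for t in self.stage_block_type):
            raise ValueError("stage_block_type entries must be 'conv' or 'msca'")
        if len(self.deep_supervision_weights) != self.n_stages:
            raise ValueError(
                "deep_supervision_weights length must equal the number of "
                "supervision heads (= n_stages)"
            )
        self.branch_kernels = tuple(int(k) for k in self.branch_kernels)
        self.deep_supervision_weights = tuple(
            float(w) for w in self.deep_supervision_weights
        )

    @classmethod
    def tiny(cls, **kw) -> "ArchConfig":
        """Desk-scale preset used by tests and the synthetic studies."""
        kw.setdefault("stage_channels", TINY_STAGE_CHANNELS)
        return cls(**kw)

    @property
    def max_downsampling(self) -> int:
        return 2 ** self.n_stages


@dataclass
class StageOutputs:
    """Deep-supervision probability maps, lowest resolution first."""

    outputs: list
    scale_factors: list[int]

    def __len__(self):
        return len(self.outputs)


# -- module system -----------------------------------------------------


class Module:
    """Minimal parameter container with recursive traversal."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state size mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p.data = np.asarray(a, dtype=PARAM_DTYPE).copy()


def _he(rng, shape, fan_in) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(PARAM_DTYPE)


class Conv3d(Module):
    """Stride-1 same-padded convolution with odd (possibly 1x1x1) kernel."""

    def __init__(self, rng, c_in, c_out, kernel=3):
        k = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        fan_in = c_in * int(np.prod(k))
        self.weight = Parameter(_he(rng, k + (c_in, c_out), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=PARAM_DTYPE))

    def __call__(self, x):
        return grad.conv3d(x, self.weight, self.bias)


class ConvDown(Module):
    """2x2x2 stride-2 convolution (downsampling by 2)."""

    def __init__(self, rng, c_in, c_out):
        self.weight = Parameter(_he(rng, (2, 2, 2, c_in, c_out), c_in * 8))
        self.bias = Parameter(np.zeros(c_out, dtype=PARAM_DTYPE))

    def __call__(self, x):
        return grad.conv_down2(x, self.weight, self.bias)


class ConvUp(Module):
    """2x2x2 stride-2 transposed convolution (strided deconvolution)."""

    def __init__(self, rng, c_in, c_out):
        self.weight = Parameter(_he(rng, (c_in, 2, 2, 2, c_out), c_in))
        self.bias = Parameter(np.zeros(c_out, dtype=PARAM_DTYPE))

    def __call__(self, x):
        return grad.conv_up2(x, self.weight, self.bias)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over spatial locations."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=PARAM_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=PARAM_DTYPE))
        self.eps = eps

    def __call__(self, x):
        x = as_tensor(x)
        if int(np.prod(x.shape[1:4])) == 1:
            # a single spatial voxel has no sample statistics; normalizing
            # would collapse the feature to beta regardless of input
            return self.gamma * x + self.beta
        return grad.instance_norm(x, self.gamma, self.beta, self.eps, axes=(1, 2, 3))


class MSCA3D(Module):
    """The 3D multiscale convolutional attention op (see module docstring).

    Operates on channels-last feature maps (N, D, H, W, C).
    """

    def __init__(self, params: MSCAParams, rng=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params = params
        C = params.channels
        k = params.dw_kernel
        self.dw_weight = Parameter(_he(rng, (C, k, k, k), k ** 3))
        self.dw_bias = Parameter(np.zeros(C, dtype=PARAM_DTYPE))
        self.branch_weights = []
        for bk in params.branch_kernels:
            triple = [Parameter(_he(rng, (C, bk), bk)) for _ in range(3)]
            self.branch_weights.append(triple)
        self.proj = Conv3d(rng, C, C, kernel=1)

    def __call__(self, x):
        x = as_tensor(x)
        if x.shape[-1] != self.params.channels:
            raise ValueError(
                f"expected {self.params.channels} channels, got {x.shape[-1]}"
            )
        a = grad.dw_conv3(x, self.dw_weight) + self.dw_bias
        acc = a if self.params.include_identity_branch else Tensor(np.zeros_like(a.data))
        for w0, w1, w2 in self.branch_weights:
            t = grad.dw_conv_axis(a, w0, 1)
            t = grad.dw_conv_axis(t, w1, 2)
            t = grad.dw_conv_axis(t, w2, 3)
            acc = acc + t
        attention = self.proj(acc)
        return attention * x


def msca_block(X, params: MSCAParams, seed: int = 0, module: MSCA3D | None = None):
    """Functional MSCA attention on a channels-first (C, D, H, W) grid.

    A convenience wrapper around :class:`MSCA3D`; pass ``module`` to reuse
    weights, otherwise they are freshly initialized from ``seed``.
    """
    X = as_tensor(X)
    if X.ndim != 4:
        raise ValueError(f"expected a rank-4 (C, D, H, W) grid, got rank {X.ndim}")
    if X.shape[0] != params.channels:
        raise ValueError(
            f"channel mismatch: input has {X.shape[0]}, params expect {params.channels}"
        )
    module = module or MSCA3D(params, np.random.default_rng(seed))
    y = module(grad.transpose(X, (1, 2, 3, 0)).reshape((1,) + X.shape[1:] + (X.shape[0],)))
    y = y.reshape(tuple(y.shape[1:]))
    return grad.transpose(y, (3, 0, 1, 2))


class ConvBlock(Module):
    """[conv3 -> InstanceNorm -> leaky ReLU] x 2."""

    def __init__(self, rng, c_in, c_out, eps=1e-5):
        self.conv1 = Conv3d(rng, c_in, c_out, 3)
        self.norm1 = InstanceNorm(c_out, eps)
        self.conv2 = Conv3d(rng, c_out, c_out, 3)
        self.norm2 = InstanceNorm(c_out, eps)

    def __call__(self, x):
        x = grad.leaky_relu(self.norm1(self.conv1(x)))
        return grad.leaky_relu(self.norm2(self.conv2(x)))


class MSCABlock(Module):
    """conv3 -> InstanceNorm -> GELU local embedding, then MSCA attention."""

    def __init__(self, rng, c_in, c_out, arch: "ArchConfig"):
        self.conv = Conv3d(rng, c_in, c_out, 3)
        self.norm = InstanceNorm(c_out, arch.norm_eps)
        self.attn = MSCA3D(
            MSCAParams(
                channels=c_out,
                dw_kernel=arch.dw_kernel,
                branch_kernels=arch.branch_kernels,
            ),
            rng,
        )

    def __call__(self, x):
        h = grad.gelu(self.norm(self.conv(x)))
        return h + self.attn(h)  # residual keeps the attention reweighting stable


def _make_block(rng, kind, c_in, c_out, cfg: ArchConfig) -> Module:
    if kind == "msca":
        return MSCABlock(rng, c_in, c_out, cfg)
    return ConvBlock(rng, c_in, c_out, cfg.norm_eps)


class Network(Module):
    """The assembled encoder-decoder; built by :func:`build_network`."""

    def __init__(self, cfg: ArchConfig, rng):
        self.cfg = cfg
        ch = cfg.stage_channels
        # full-resolution stem (plain convolution)
        self.stem = ConvBlock(rng, cfg.in_channels, ch[0], cfg.norm_eps)
        # encoder: downsample + stage block per stage
        self.downs: list[Module] = []
        self.enc_blocks: list[Module] = []
        prev = ch[0]
        for i in range(cfg.n_stages):
            self.downs.append(ConvDown(rng, prev, ch[i]))
            self.enc_blocks.append(_make_block(rng, cfg.stage_block_type[i], ch[i], ch[i], cfg))
            prev = ch[i]
        # decoder: mirror resolutions; skip channels come from the encoder
        skip_channels = [ch[0]] + list(ch[:-1])  # stem, stage1..stage4 outputs
        skip_types = ["conv"] + list(cfg.stage_block_type[:-1])
        self.ups: list[Module] = []
        self.dec_blocks: list[Module] = []
        self.heads: list[Module] = []
        prev = ch[-1]
        for i in reversed(range(cfg.n_stages)):  # deepest decoder level first
            c_skip = skip_channels[i]
            self.ups.append(ConvUp(rng, prev, c_skip))
            self.dec_blocks.append(_make_block(rng, skip_types[i], 2 * c_skip, c_skip, cfg))
            head = Conv3d(rng, c_skip, cfg.n_classes, 1)
            # zero-initialized heads start every prediction at the uniform
            # distribution, which keeps the first optimizer steps mild
            head.weight.data[:] = 0.0
            self.heads.append(head)
            prev = c_skip

    def forward(self, x) -> list[Tensor]:
        """Probability maps per supervision head, lowest resolution first.

        ``x``: channels-last (N, D, H, W, in_channels) with spatial extents
        divisible by ``cfg.max_downsampling``; outputs are channels-first
        (N, n_classes, d, h, w), softmax-normalized over the class axis.
        """
        x = as_tensor(x)
        div = self.cfg.max_downsampling
        if any(s % div for s in x.shape[1:4]):
            raise ValueError(
                f"spatial extents {tuple(x.shape[1:4])} must be divisible by {div}"
            )
        skips = []
        h = self.stem(x)
        skips.append(h)
        for down, block in zip(self.downs, self.enc_blocks):
            h = block(down(h))
            skips.append(h)
        probs: list[Tensor] = []
        h = skips[-1]
        for up, block, head, skip in zip(
            self.ups, self.dec_blocks, self.heads, reversed(skips[:-1])
        ):
            h = block(grad.concat([up(h), skip], axis=-1))
            logits = grad.transpose(head(h), (0, 4, 1, 2, 3))
            probs.append(grad.softmax(logits, axis=1))
        return probs

    def scale_factors(self) -> list[int]:
        return [2 ** (self.cfg.n_stages - 1 - i) for i in range(self.cfg.n_stages)]


def build_network(cfg: ArchConfig, seed: int = 0) -> Network:
    """Assemble the network with deterministic He-initialized parameters."""
    return Network(cfg, np.random.default_rng(seed))


def forward_pass(net: Network, patch: np.ndarray) -> StageOutputs:
    """Run a single 3D patch through the network.

    Returns per-head probability maps (K, d, h, w) as numpy arrays, lowest
    resolution first, the final head at the input resolution.
    """
    patch = np.asarray(patch, dtype=PARAM_DTYPE)
    if patch.ndim != 3:
        raise ValueError(f"expected a rank-3 patch, got rank {patch.ndim}")
    probs = net.forward(Tensor(patch[None, ..., None]))
    return StageOutputs(
        outputs=[p.data[0] for p in probs], scale_factors=net.scale_factors()
    )


def describe(cfg: ArchConfig, seed: int = 0) -> list[dict]:
    """Stage table: resolution factor, channels, block type, parameter count."""
    net = build_network(cfg, seed)
    rows = [
        {
            "level": "stem",
            "downsampling": 1,
            "channels": cfg.stage_channels[0],
            "block": "conv",
            "params": sum(p.data.size for p in net.stem.parameters()),
        }
    ]
    for i in range(cfg.n_stages):
        n = sum(p.data.size for p in net.downs[i].parameters())
        n += sum(p.data.size for p in net.enc_blocks[i].parameters())
        rows.append(
            {
                "level": f"stage{i + 1}" + (" (bottleneck)" if i == cfg.n_stages - 1 else ""),
                "downsampling": 2 ** (i + 1),
                "channels": cfg.stage_channels[i],
                "block": cfg.stage_block_type[i],
                "params": n,
            }
        )
    dec_params = sum(
        sum(p.data.size for p in m.parameters())
        for group in (net.ups, net.dec_blocks, net.heads)
        for m in group
    )
    rows.append(
        {
            "level": "decoder+heads",
            "downsampling": 1,
            "channels": "-",
            "block": "mirrored",
            "params": dec_params,
        }
    )
    rows.append(
        {
            "level": "total",
            "downsampling": "-",
            "channels": "-",
            "block": "-",
            "params": net.n_parameters(),
        }
    )
    return rows
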