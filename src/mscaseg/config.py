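"""YAML configuration and checkpoint serialization.

A configuration file holds up to five sections — ``train``, ``arch``,
``loss``, ``canny`` and ``phantom`` — mirroring the corresponding dataclass
fields one-for-one.  Phantom bias-field coefficients are written as
``[px, py, pz, value]`` rows because YAML has no tuple keys.

Checkpoints are numpy ``.npz`` archives holding the flattened parameter list
plus a JSON header with the full configuration and the training seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .arch import ArchConfig, Network, build_network
from .edges import CannyParams
from .losses import LossConfig
from .phantom import PhantomConfig
from .train import TrainConfig

_SECTIONS = {
    "train": TrainConfig,
    "arch": ArchConfig,
    "loss": LossConfig,
    "canny": CannyParams,
    "phantom": PhantomConfig,
}


def _to_plain(obj):
    if isinstance(obj, PhantomConfig):
        d = dataclasses.asdict(obj)
        d["bias_coeffs"] = [
            [int(px), int(py), int(pz), float(c)]
            for (px, py, pz), c in obj.bias_coeffs.items()
        ]
        return d
    d = dataclasses.asdict(obj)
    return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}


def _from_plain(cls, d: dict):
    d = dict(d)
    if cls is PhantomConfig and "bias_coeffs" in d:
        d["bias_coeffs"] = {
            (int(px), int(py), int(pz)): float(c) for px, py, pz, c in d["bias_coeffs"]
        }
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**d)


def config_to_dict(**sections) -> dict:
    """Serialize config dataclasses (train=..., arch=..., ...) to a dict."""
    out = {}
    for name, obj in sections.items():
        if name not in _SECTIONS:
            raise ValueError(f"unknown config section: {name}")
        if obj is not None:
            out[name] = _to_plain(obj)
    return out


def config_from_dict(d: dict) -> dict:
    """Inverse of :func:`config_to_dict`; missing sections get defaults."""
    out = {}
    for name, cls in _SECTIONS.items():
        out[name] = _from_plain(cls, d.get(name, {}) or {})
    return out


def save_config(path, **sections) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(**sections), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def save_checkpoint(path, net: Network, train_cfg: TrainConfig | None = None) -> None:
    """Write network parameters plus configuration to a ``.npz`` archive."""
    header = {
        "arch": _to_plain(net.cfg),
        "train": _to_plain(train_cfg) if train_cfg is not None else None,
        "seed": getattr(train_cfg, "seed", None),
    }
    arrays = {f"param_{i}": a for i, a in enumerate(net.state_dict())}
    np.savez_compressed(path, header=json.dumps(header), **arrays)


def load_checkpoint(path) -> tuple[Network, TrainConfig | None]:
    with np.load(path, allow_pickle=False) as npz:
        header = json.loads(str(npz["header"]))
        arrays = [npz[f"param_{i}"] for i in range(len(npz.files) - 1)]
    arch = _from_plain(ArchConfig, header["arch"])
    net = build_network(arch, seed=0)
    net.load_state_dict(arrays)
    train_cfg = (
        _from_plain(TrainConfig, header["train"]) if header.get("train") else None
    )
    return net, train_cfg
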