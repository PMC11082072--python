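"""Layered run configuration: defaults ← YAML file ← key=value overrides.

Every run writes a resolved-config copy, the seed, and a library-version
manifest next to its outputs, which together suffice to rerun the
computation bit-compatibly in deterministic (single-thread) mode.
"""

from __future__ import annotations

import json
import platform
import sys
from dataclasses import asdict
from pathlib import Path
from typing import Any, Optional

import yaml

from .losses import LossWeights
from .model import EncoderConfig
from .training import GridSpec, TrainConfig


class ConfigError(ValueError):
    pass


_DEFAULTS: dict[str, dict[str, Any]] = {
    "data": {
        "train_path": None,
        "test_path": None,
        "max_len": 64,
    },
    "model": {k: v for k, v in asdict(EncoderConfig()).items()},
    "loss": {
        "alpha": 0.0,
        "beta": 0.5,
        "tau": 0.2,
        "include_positive_in_denominator": False,
        "symmetric": False,
        "reduction": "mean",
    },
    "train": {
        "learning_rate": 1e-3,
        "epochs": 50,
        "batch_size": 32,
        "val_fraction": 0.1,
        "select_epoch_by_val_mcc": False,
    },
    "grid": {
        "alphas": [0.0, 0.1, 0.3, 0.5, 0.7, 0.9],
        "betas": [0.0, 0.5, 1.0],
        "taus": [0.05, 0.1, 0.2, 0.5, 1.0],
        "seeds": [0, 1, 2, 3, 4, 5, 6],
        "architectures": ["cnn", "lstm", "transformer"],
    },
    "audit": {
        "threshold": 1e-5,
        "backend": "builtin",
    },
    "explain": {
        "n_steps": 64,
        "baseline": "pad",
        "tower": 1,
    },
    "seed": 0,
    "out_dir": "runs",
}


def _deep_merge(base: dict, update: dict, path: str = "") -> dict:
    out = dict(base)
    for key, value in update.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key {here!r}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {here!r} must be a mapping")
            out[key] = _deep_merge(base[key], value, here)
        else:
            out[key] = value
    return out


def _parse_scalar(text: str) -> Any:
    return yaml.safe_load(text)


def apply_overrides(config: dict, overrides: list[str]) -> dict:
    """Apply ``section.key=value`` overrides after file config."""
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not key=value")
        key_path, raw = item.split("=", 1)
        keys = key_path.strip().split(".")
        node: dict = {}
        leaf = node
        for k in keys[:-1]:
            leaf[k] = {}
            leaf = leaf[k]
        leaf[keys[-1]] = _parse_scalar(raw)
        config = _deep_merge(config, node)
    return config


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[list[str]] = None) -> dict:
    config = json.loads(json.dumps(_DEFAULTS))  # deep copy
    if path is not None:
        with Path(path).open() as fh:
            file_cfg = yaml.safe_load(fh) or {}
        if not isinstance(file_cfg, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        config = _deep_merge(config, file_cfg)
    if overrides:
        config = apply_overrides(config, overrides)
    return config


def encoder_config_from(config: dict) -> EncoderConfig:
    model = dict(config["model"])
    model["max_len"] = config["data"]["max_len"]
    return EncoderConfig(**model)


def train_config_from(config: dict) -> TrainConfig:
    loss = config["loss"]
    train = config["train"]
    return TrainConfig(
        learning_rate=train["learning_rate"],
        epochs=train["epochs"],
        batch_size=train["batch_size"],
        seed=config["seed"],
        val_fraction=train["val_fraction"],
        weights=LossWeights(alpha=loss["alpha"], beta=loss["beta"],
                            tau=loss["tau"]),
        model=encoder_config_from(config),
        select_epoch_by_val_mcc=train["select_epoch_by_val_mcc"],
        loss_reduction=loss["reduction"],
        include_positive_in_denominator=loss["include_positive_in_denominator"],
        symmetric_contrastive=loss["symmetric"],
    )


def grid_spec_from(config: dict) -> GridSpec:
    g = config["grid"]
    return GridSpec(alphas=tuple(g["alphas"]), betas=tuple(g["betas"]),
                    taus=tuple(g["taus"]), seeds=tuple(g["seeds"]),
                    architectures=tuple(g["architectures"]))


def write_run_manifest(config: dict, out_dir: str | Path) -> None:
    """Persist resolved config, seed, and library versions next to outputs."""
    import numpy
    import pandas
    import scipy
    import sklearn
    import Bio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with (out_dir / "resolved_config.yaml").open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    manifest = {
        "python": sys.version,
        "platform": platform.platform(),
        "seed": config["seed"],
        "versions": {
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "biopython": Bio.__version__,
        },
    }
    with (out_dir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
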