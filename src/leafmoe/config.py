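"""Run configuration: defaults < YAML file < dotted command-line overrides.

The configuration tree mirrors the package's components (backbone, noise,
moe, loss, train, synth, curation).  Unknown keys are rejected rather than
ignored — a typo in an experiment config should fail loudly — and every run
writes its fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .backbone import NoiseConfig
from .moe import MoEConfig
from .objectives import LossWeights
from .trainer import TrainConfig

__all__ = ["BackboneConfig", "SynthConfig", "CurationConfig", "RunConfig",
           "load_config", "save_config"]


@dataclass
class BackboneConfig:
    name: str = "tiny-vit"
    image_size: int = 64
    patch_size: int = 8
    dim: int = 32
    depth: int = 2
    heads: int = 4
    pooling: str = "cls_token"


@dataclass
class SynthConfig:
    n_classes: int = 6
    images_per_class: int = 100
    image_size: int = 64
    severity: float = 0.7
    redundancy_factor: int = 1
    domain: str = "lab"


@dataclass
class CurationConfig:
    extractor: str = "pixel"
    n_per_class: int = 100
    perplexity: float = 30.0
    learning_rate: float = 500.0


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/latest"
    log_level: str = "INFO"
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    moe: MoEConfig = field(default_factory=MoEConfig)
    loss: LossWeights = field(default_factory=LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)

    def validate(self) -> "RunConfig":
        if not 1 <= self.moe.top_k <= self.moe.num_experts:
            raise ValueError(f"moe.top_k={self.moe.top_k} out of range for "
                             f"{self.moe.num_experts} experts")
        if self.backbone.image_size % self.backbone.patch_size:
            raise ValueError("backbone.image_size must be divisible by patch_size")
        return self


def _coerce(value, template):
    if isinstance(template, bool):
        if isinstance(value, bool):
            return value
        if isinstance(value, str):
            return value.lower() in ("1", "true", "yes", "on")
        return bool(value)
    if isinstance(template, int) and not isinstance(template, bool):
        return int(value)
    if isinstance(template, float):
        return float(value)
    if isinstance(template, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    return value


def _apply(obj, updates: dict, path: str = ""):
    for key, value in updates.items():
        where = f"{path}{key}"
        if not dataclasses.is_dataclass(obj) or key not in {
                f.name for f in dataclasses.fields(obj)}:
            raise KeyError(f"unknown config key: {where}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _apply(current, value, where + ".")
        elif dataclasses.is_dataclass(current):
            raise TypeError(f"{where} is a section, not a value")
        else:
            setattr(obj, key, _coerce(value, current))


def _nest(flat: dict[str, object]) -> dict:
    tree: dict = {}
    for dotted, value in flat.items():
        node = tree
        *parents, leaf = dotted.split(".")
        for part in parents:
            node = node.setdefault(part, {})
        node[leaf] = value
    return tree


def load_config(path: str | Path | None = None,
                overrides: dict[str, object] | None = None) -> RunConfig:
    """Build a validated RunConfig; precedence defaults < file < overrides.

    ``overrides`` maps dotted paths (``"moe.top_k"``) to values; strings are
    coerced to the field's type.
    """
    cfg = RunConfig()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        loaded = yaml.safe_load(path.read_text()) or {}
        if not isinstance(loaded, dict):
            raise TypeError(f"config root must be a mapping: {path}")
        _apply(cfg, loaded)
    if overrides:
        _apply(cfg, _nest(dict(overrides)))
    # objectives/trainer share the loss weights
    cfg.train.loss = cfg.loss
    return cfg.validate()


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    """Write the resolved configuration as YAML beside a run's outputs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))
    return path
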