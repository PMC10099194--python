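"""Run configuration: nested sections, YAML loading, dotted overrides.

A single global seed fans out to named substreams (dataset generation,
model init, training, sampling) so one integer reproduces a whole run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, is_dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .model import BackboneConfig
from .preprocessing import SamplerConfig
from .training import TrainConfig
from .fusion import FusionConfig
from .synthetic import DatasetConfig, RenderParams

__all__ = ["PreprocessConfig", "ClassifierConfig", "RunConfig", "load_config", "config_hash", "substream_seed"]


@dataclass
class PreprocessConfig:
    out_size: int = 64
    train_sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(mode="random_within_segment")
    )
    eval_sampler: SamplerConfig = field(
        default_factory=lambda: SamplerConfig(mode="deterministic_center")
    )


@dataclass
class ClassifierConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    l2_coefficient: float = 1e-4
    class_weight_cap: float = 10.0


@dataclass
class RunConfig:
    """Top-level configuration binding all pipeline stages.

    The micro-profile defaults are the package's desk-scale study
    conditions: 10 subjects x 20 clips of 16 frames at 64 px, a three-stage
    micro TSM backbone on 8 sampled frames, and a 5-clip fusion window.
    """

    seed: int = 0
    out_dir: str = "runs/run0"
    clip_seconds: float = 0.64  # 16-frame clip hop at 25 fps
    synthetic: DatasetConfig = field(default_factory=DatasetConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierConfig = field(
        default_factory=lambda: ClassifierConfig(
            train=TrainConfig(learning_rate=0.02, epochs=30, batch_size=8)
        )
    )
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def fan_out_seeds(self) -> "RunConfig":
        """Derive per-stage seeds from the global one (named substreams)."""
        self.synthetic.seed = substream_seed(self.seed, "synthetic")
        self.classifier.backbone.seed = substream_seed(self.seed, "model-init")
        self.classifier.train.seed = substream_seed(self.seed, "train")
        self.preprocessing.train_sampler.seed = substream_seed(self.seed, "sampler")
        return self


def substream_seed(seed: int, name: str) -> int:
    """Deterministic < 2**31 substream seed from (seed, stage name)."""
    h = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _build(cls, data: dict):
    kwargs = {}
    field_types = {f.name: f for f in fields(cls)}
    for key, val in data.items():
        if key not in field_types:
            raise ValueError(f"unknown config key {key!r} for {cls.__name__}")
        default = field_types[key].default_factory() if field_types[key].default_factory is not None and callable(field_types[key].default_factory) else None  # type: ignore[misc]
        sub_cls = type(default) if is_dataclass(default) else None
        if sub_cls is not None and isinstance(val, dict):
            merged = {**asdict(default), **val}
            kwargs[key] = _build(sub_cls, merged)
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(
    path: str | Path | None = None, overrides: "list[str] | None" = None
) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus dotted overrides.

    Overrides look like ``classifier.train.epochs=10``; values parse as
    YAML scalars. Per-stage seeds are fanned out from the global seed
    afterwards.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        data = loaded
    for ov in overrides or []:
        if "=" not in ov:
            raise ValueError(f"override {ov!r} is not of the form a.b=value")
        dotted, raw = ov.split("=", 1)
        node = data
        keys = dotted.strip().split(".")
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ValueError(f"override {ov!r} descends into a scalar")
        node[keys[-1]] = yaml.safe_load(raw)
    cfg = _build(RunConfig, data)
    return cfg.fan_out_seeds()


def _jsonable(obj):
    if is_dataclass(obj):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the scientific configuration.

    The output directory is excluded: two runs of the same experiment in
    different locations are the same experiment.
    """
    payload = _jsonable(cfg)
    payload.pop("out_dir", None)
    canon = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
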