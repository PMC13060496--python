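"""YAML (de)serialization of run configurations and provenance helpers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .nn import UNetConfig
from .synth import SynthConfig
from .training import TrainConfig


def _tuplify(value):
    if isinstance(value, list):
        return tuple(_tuplify(v) for v in value)
    return value


def synth_config_from_dict(d: dict) -> SynthConfig:
    return SynthConfig(**{k: _tuplify(v) for k, v in d.items()})


def train_config_from_dict(d: dict) -> TrainConfig:
    return TrainConfig(**d)


def unet_config_from_dict(d: dict) -> UNetConfig:
    return UNetConfig(**d)


@dataclass
class RunConfig:
    """Bundled generator + training + network configuration with a seed."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return {"synth": self.synth.to_dict(), "train": self.train.to_dict(),
                "unet": self.unet.to_dict(), "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(synth=synth_config_from_dict(d.get("synth", {})),
                   train=train_config_from_dict(d.get("train", {})),
                   unet=unet_config_from_dict(d.get("unet", {})),
                   seed=int(d.get("seed", 0)))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())


def config_hash(d: dict) -> str:
    """Short stable hash of a configuration dictionary (provenance)."""
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
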