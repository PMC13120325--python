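"""Run configuration: YAML round-trip, seed derivation, config hashing.

A single global seed deterministically spawns the per-stage seeds
(simulation, split, init/shuffle) through a fixed ``SeedSequence``
derivation, so any stage can be reproduced in isolation.  The configuration
round-trips losslessly through YAML and is identified in logs by a short
content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .phantom_sim import GLYPH_KINDS, PhantomParams
from .quality_metrics import MetricParams
from .train import TrainConfig
from .unet import UNetConfig, get_config

SCHEMA_VERSION = 1

_STAGES = ("simulate", "split", "init", "shuffle")


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Spawn one sub-2^31 seed per pipeline stage from the global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(len(_STAGES))
    return {stage: int(s % (2 ** 31)) for stage, s in zip(_STAGES, state)}


@dataclass
class RunConfig:
    """Everything one end-to-end run needs; YAML-serializable."""

    seed: int = 0
    version: int = SCHEMA_VERSION
    out_dir: str = "run"
    log_level: str = "INFO"
    n_pairs: int = 200
    image_size: int = 96
    glyph_kinds: tuple[str, ...] = GLYPH_KINDS
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    unet: UNetConfig = field(default_factory=lambda: get_config("small512"))
    training: TrainConfig = field(default_factory=TrainConfig)
    metrics: MetricParams = field(default_factory=MetricParams)
    wiener_window: int = 5
    wiener_noise_power: float | None = None

    def __post_init__(self):
        if self.version != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported config version {self.version}")
        self.glyph_kinds = tuple(self.glyph_kinds)
        self.fractions = tuple(self.fractions)
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["glyph_kinds"] = list(self.glyph_kinds)
        d["fractions"] = list(self.fractions)
        d["unet"]["encoder_channels"] = list(self.unet.encoder_channels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["phantom"] = PhantomParams.from_dict(d["phantom"])
        d["unet"] = UNetConfig.from_dict(d["unet"])
        d["training"] = TrainConfig.from_dict(d["training"])
        d["metrics"] = MetricParams(**d["metrics"])
        d["glyph_kinds"] = tuple(d["glyph_kinds"])
        d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        return cls.from_dict(yaml.safe_load(text))

    @property
    def hash(self) -> str:
        """Short content hash identifying this configuration in logs."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:10]
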