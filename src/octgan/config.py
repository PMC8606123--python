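"""Run configuration: YAML round-trip with strict (unknown-key) validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .gan import DiscriminatorSpec, GeneratorSpec, LossConfig
from .phantoms import AcquisitionConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]

SCHEMA_VERSION = 1


def _build(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = dict(data)
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            kwargs[f.name] = tuple(kwargs[f.name])
    return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """Merged simulator + training + evaluation configuration."""

    seed: int = 0
    counts: dict = field(default_factory=lambda: {"beads": 0, "tape": 0,
                                                  "tissue": 0})
    pair_mode: str = "synthetic-gap"
    test_fraction: float = 0.2
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminator: DiscriminatorSpec = field(default_factory=DiscriminatorSpec)

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "counts": dict(self.counts),
            "pair_mode": self.pair_mode,
            "test_fraction": self.test_fraction,
            "acquisition": asdict(self.acquisition),
            "train": asdict(self.train),
            "loss": asdict(self.loss),
            "generator": asdict(self.generator),
            "discriminator": asdict(self.discriminator),
        }


def save_config(cfg: RunConfig, path) -> None:
    data = cfg.to_dict()
    for key in ("train", "loss", "acquisition", "generator", "discriminator"):
        data[key] = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in data[key].items()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    version = data.pop("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ValueError(f"config schema version {version}, "
                         f"expected {SCHEMA_VERSION}")
    known = {"seed", "counts", "pair_mode", "test_fraction", "acquisition",
             "train", "loss", "generator", "discriminator"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key in ("seed", "counts", "pair_mode", "test_fraction"):
        if key in data:
            kwargs[key] = data[key]
    for key, cls in (("acquisition", AcquisitionConfig),
                     ("train", TrainConfig), ("loss", LossConfig),
                     ("generator", GeneratorSpec),
                     ("discriminator", DiscriminatorSpec)):
        if key in data:
            kwargs[key] = _build(cls, data[key])
    return RunConfig(**kwargs)
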