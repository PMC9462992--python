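"""YAML run configuration: schema-validated sections mapped onto the
dataclass configs of the phantom, network, trainer and geometry stages.
Unknown keys are rejected so typos fail fast."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossWeights
from .mtunet import NetworkConfig
from .phantom import PhantomSpec, spec_from_dict
from .trainer import TrainConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class DatasetConfig:
    n_standard: int = 60
    n_nonstandard: int = 40
    n_patients: int = 10


@dataclass(frozen=True)
class GeometryConfig:
    tangent_rule: str = "max-angle"      # or "min-angle"
    fh_class: int = 2

    def __post_init__(self):
        if self.tangent_rule not in ("max-angle", "min-angle"):
            raise ValueError(f"unknown tangent_rule {self.tangent_rule!r}")


@dataclass(frozen=True)
class EvalConfig:
    pixel_spacing_mm: float = 0.2
    plots: bool = False


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    target_height: int = 96
    target_width: int = 96
    output_dir: str = "runs"
    verbosity: int = 1

    @property
    def target_size(self):
        return (self.target_height, self.target_width)


def _build(cls, data: dict, name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


_SECTIONS = {
    "phantom": None,  # handled by spec_from_dict (nested tuples)
    "dataset": DatasetConfig,
    "network": NetworkConfig,
    "train": TrainConfig,
    "geometry": GeometryConfig,
    "evaluation": EvalConfig,
}
_SCALARS = {"target_height", "target_width", "output_dir", "verbosity"}


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - _SCALARS
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {k: raw[k] for k in _SCALARS if k in raw}
    if "phantom" in raw:
        known = {f.name for f in dataclasses.fields(PhantomSpec)}
        bad = set(raw["phantom"]) - known
        if bad:
            raise ValueError(f"unknown keys in section 'phantom': {sorted(bad)}")
        kwargs["phantom"] = spec_from_dict(raw["phantom"])
    for name, cls in _SECTIONS.items():
        if cls is not None and name in raw:
            section = dict(raw[name])
            if name == "train" and "weights" in section:
                section["weights"] = _build(LossWeights, section["weights"],
                                            "train.weights")
            kwargs[name] = _build(cls, section, name)
    return RunConfig(**kwargs)


def dump_config(cfg: RunConfig, path) -> None:
    """Copy the effective configuration next to a run's outputs."""
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [enc(v) for v in obj]
        return obj
    data = {name: enc(getattr(cfg, name)) for name in _SECTIONS}
    data.update({k: getattr(cfg, k) for k in _SCALARS})
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
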