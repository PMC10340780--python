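"""Structured run configuration.

A :class:`RunConfig` holds one section per pipeline stage; YAML (or JSON)
files map onto it section by section.  Unknown keys are rejected anywhere
in the tree, and every run logs the fully-resolved configuration together
with a content hash so any artifact on disk is reproducible from
``(config, seed, code version)``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .finetune import DEFAULT_ARCH, FractionExperimentSpec
from .insertion import InsertionModel
from .phantoms import PhantomConfig
from .shapes import LesionConfig
from .training import TrainConfig


@dataclass
class CohortConfig:
    n_train_per_class: int = 50
    n_val_per_class: int = 40
    n_per_slice: int = 2
    negative_fraction: float = 0.25


@dataclass
class EvalConfig:
    alpha: float = 0.05
    positive: str = "cancer"


@dataclass
class PathsConfig:
    out_dir: str = "runs"


def _from_mapping(cls, data: dict, where: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"{where}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(f"{where}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        kwargs[k] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


@dataclass
class RunConfig:
    seed: int = 0
    arch_id: str = DEFAULT_ARCH
    phantoms: PhantomConfig = field(default_factory=PhantomConfig)
    lesion: LesionConfig = field(default_factory=LesionConfig)
    insertion: InsertionModel = field(default_factory=InsertionModel)
    pretext: TrainConfig = field(default_factory=TrainConfig)
    finetune: TrainConfig = field(default_factory=TrainConfig)
    experiment: FractionExperimentSpec = field(default_factory=FractionExperimentSpec)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    paths: PathsConfig = field(default_factory=PathsConfig)

    _SECTIONS = {
        "phantoms": PhantomConfig,
        "lesion": LesionConfig,
        "insertion": InsertionModel,
        "pretext": TrainConfig,
        "finetune": TrainConfig,
        "experiment": FractionExperimentSpec,
        "cohort": CohortConfig,
        "eval": EvalConfig,
        "paths": PathsConfig,
    }

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._SECTIONS) - {"seed", "arch_id"}
        if unknown:
            raise ConfigurationError(f"config: unknown top-level keys {sorted(unknown)}")
        kwargs = {}
        for key in ("seed", "arch_id"):
            if key in data:
                kwargs[key] = data[key]
        for name, section_cls in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _from_mapping(section_cls, data[name], where=name)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_mapping(data)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write_run_log(self, out_dir, extra: dict | None = None) -> Path:
        from . import __version__

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = {
            "config": self.resolved(),
            "config_hash": self.content_hash(),
            "seed": self.seed,
            "version": __version__,
        }
        payload.update(extra or {})
        path = out / "run_log.json"
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        return path
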