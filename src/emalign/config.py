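"""Run configuration: one flat, key-namespaced YAML mapping.

Every stage parameter has a documented default on its dataclass
(:class:`~emalign.rigid.RigidParams`, :class:`~emalign.flow.FlowParams`,
elastic/evaluation/tiling settings below); a config file only needs the
keys it overrides.  Keys are namespaced ``stage.param`` (e.g.
``flow.smoothness``), CLI flags override the file, and a written config
reads back equal — so any run is reproducible from its config + seed.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields

import yaml

from .evaluation import EvalParams
from .flow import FlowParams
from .rigid import RigidParams

__all__ = ["ElasticConfig", "TileConfig", "RunConfig"]

logger = logging.getLogger("emalign")


@dataclass
class ElasticConfig:
    sigma_z: float = 1.0     # Gaussian sigma along z, in slice units
    radius: int = 1          # kernel radius (stack registration supports 1)
    sweeps: int = 1
    boundary: str = "one-sided"


@dataclass
class TileConfig:
    patch: int = 1024
    overlap: int = 128


@dataclass
class RunConfig:
    rigid: RigidParams = field(default_factory=RigidParams)
    flow: FlowParams = field(default_factory=FlowParams)
    elastic: ElasticConfig = field(default_factory=ElasticConfig)
    evaluation: EvalParams = field(default_factory=EvalParams)
    tile: TileConfig = field(default_factory=TileConfig)
    seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = ("rigid", "flow", "elastic", "evaluation", "tile")

    def to_dict(self) -> dict:
        """Flat ``section.param -> value`` mapping (detector objects excluded)."""
        out: dict = {"seed": self.seed, "log_level": self.log_level}
        for section in self._SECTIONS:
            for key, value in asdict(getattr(self, section)).items():
                if key == "detector":
                    continue
                if isinstance(value, tuple):
                    value = [list(v) if isinstance(v, tuple) else v for v in value]
                out[f"{section}.{key}"] = value
        return out

    @classmethod
    def from_dict(cls, flat: dict) -> "RunConfig":
        cfg = cls()
        known = {}
        for section in cls._SECTIONS:
            obj = getattr(cfg, section)
            known[section] = {f.name for f in fields(obj)}
        for key, value in flat.items():
            if key == "seed":
                cfg.seed = int(value)
                continue
            if key == "log_level":
                cfg.log_level = str(value)
                continue
            if "." not in key:
                raise ValueError(f"unknown config key {key!r} (expected section.param)")
            section, param = key.split(".", 1)
            if section not in known or param not in known[section]:
                raise ValueError(f"unknown config key {key!r}")
            if isinstance(value, list):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            setattr(getattr(cfg, section), param, value)
        return cfg

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        return cls.from_dict(flat)
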