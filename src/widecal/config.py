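"""Pipeline configuration: every stage's parameter block in one validated
object, loadable from YAML or JSON.  Unknown keys are rejected."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .behavior import BehaviorParams
from .detect import DetectionParams
from .merge import MergeParams
from .preprocess import RegistrationParams
from .spatial import SpatialParams
from .synth import SimParams
from .taskstats import AnalysisParams


def _build(cls, data: dict[str, Any] | None, name: str):
    data = dict(data or {})
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown keys in {name!r} block: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


@dataclass
class PipelineConfig:
    sim: SimParams = field(default_factory=SimParams)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    merge: MergeParams = field(default_factory=MergeParams)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    seed: int = 0
    log_level: str = "INFO"

    _BLOCKS = {
        "sim": SimParams,
        "registration": RegistrationParams,
        "detection": DetectionParams,
        "merge": MergeParams,
        "behavior": BehaviorParams,
        "analysis": AnalysisParams,
        "spatial": SpatialParams,
    }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - set(cls._BLOCKS) - {"seed", "log_level"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, block_cls in cls._BLOCKS.items():
            kwargs[name] = _build(block_cls, data.get(name), name)
        cfg = cls(
            seed=int(data.get("seed", 0)),
            log_level=str(data.get("log_level", "INFO")),
            **kwargs,
        )
        # the global seed drives the simulator unless explicitly overridden
        if "sim" not in data or "seed" not in (data.get("sim") or {}):
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        if "spatial" not in data or "seed" not in (data.get("spatial") or {}):
            cfg.spatial = dataclasses.replace(cfg.spatial, seed=cfg.seed)
        return cfg

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"seed": self.seed, "log_level": self.log_level}
        for name in self._BLOCKS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
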