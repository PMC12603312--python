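"""Run configuration: YAML round-trip with strict (unknown-key-rejecting) parsing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .design import OligoDesign
from .model import CallerConfig
from .search import AMParams
from .simulate import ErrorRates, SimConfig

__all__ = ["RunConfig"]


def _from_mapping(cls, data: dict):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """All tunables of one pipeline run, grouped per stage."""

    design: OligoDesign = field(default_factory=OligoDesign)
    simulation: SimConfig = field(default_factory=SimConfig)
    error_rates: ErrorRates = field(default_factory=ErrorRates)
    search: AMParams = field(default_factory=AMParams)
    model: CallerConfig = field(default_factory=lambda: CallerConfig.reduced(n_classes=19))
    seed: int = 0
    n_blocks: int = 50
    coverage: int = 20
    min_hamming: int = 10
    label_fraction: float = 0.30
    include_spacer_tokens: bool = True
    recovery_threshold: float = 0.95

    _GROUPS = {
        "design": OligoDesign,
        "simulation": SimConfig,
        "error_rates": ErrorRates,
        "search": AMParams,
        "model": CallerConfig,
    }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"]["conv_filters"] = list(d["model"]["conv_filters"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for name, group_cls in cls._GROUPS.items():
            if name in data:
                sub = dict(data.pop(name))
                if name == "model" and "conv_filters" in sub:
                    sub["conv_filters"] = tuple(sub["conv_filters"])
                kwargs[name] = _from_mapping(group_cls, sub)
        scalars = {f.name for f in fields(cls)} - set(cls._GROUPS)
        unknown = set(data) - scalars
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        """Stable short hash identifying this configuration in output files."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
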