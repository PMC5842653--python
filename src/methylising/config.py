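"""Pipeline configuration with the published defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    region_size: int = 3000
    gu_size: int = 150
    min_cpgs: int = 10
    min_obs_fraction: float = 2.0 / 3.0
    min_depth: float = 2.5
    bandwidth: float = 50_000.0
    fdr: float = 0.01
    optimizer_budget: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name != "seed" and getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if not 0.0 < self.fdr < 1.0:
            raise ValueError("fdr must lie in (0, 1)")
        if self.region_size % self.gu_size != 0:
            raise ValueError("region_size must be divisible by gu_size")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def replace(self, **kwargs) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return PipelineConfig(**data)
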