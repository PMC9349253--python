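"""Run configuration: protocol parameters shared by the CLI subcommands."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .geometry import BlockFrame
from .localization import MEASUREMENT_GRID
from .sectioning import (
    APPROACH_MARGIN,
    FINE_THICKNESS,
    SURVEY_INTERVAL,
    TRIM_THICKNESS,
)


@dataclass(frozen=True)
class RunConfig:
    """Flat protocol configuration with the bench defaults.

    Lengths in µm, angles in degrees.  Unknown keys in a config file are
    rejected rather than silently ignored.
    """

    fine_thickness: float = FINE_THICKNESS
    trim_thickness: float = TRIM_THICKNESS
    interval: float = SURVEY_INTERVAL
    approach_margin: float = APPROACH_MARGIN
    capacity_deg: float = 20.0
    grid: float = MEASUREMENT_GRID
    jitter_sd: float = 0.0
    mirror: bool = False
    seed: int | None = None
    frame: dict | None = None  # BlockFrame.to_dict() payload, optional

    def __post_init__(self) -> None:
        for key in ("fine_thickness", "trim_thickness", "interval", "grid"):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive")
        if self.approach_margin < 0 or self.jitter_sd < 0:
            raise ConfigError("approach_margin and jitter_sd must be >= 0")
        if not (0.0 < self.capacity_deg < 90.0):
            raise ConfigError("capacity_deg must be in (0, 90)")

    def block_frame(self) -> BlockFrame | None:
        return BlockFrame.from_dict(self.frame) if self.frame else None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def override(self, **kwargs) -> "RunConfig":
        """New config with non-None keyword overrides applied (CLI flags)."""
        d = self.to_dict()
        for k, v in kwargs.items():
            if v is not None:
                d[k] = v
        return RunConfig.from_dict(d)
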