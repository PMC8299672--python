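"""Run configuration: hardware constants and planning tolerances."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .cephalometrics import FacebowConstants
from .errors import ConfigError


@dataclass(frozen=True)
class Config:
    ns_offset: float = 30.0
    axis_anterior_offset: float = 10.0
    open_rotation_deg: float = 2.0
    contact_tolerance: float = 0.1

    @property
    def facebow_constants(self) -> FacebowConstants:
        return FacebowConstants(
            ns_offset=self.ns_offset, axis_anterior_offset=self.axis_anterior_offset
        )

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path=None) -> Config:
    """Load a JSON config; absent file/keys fall back to defaults.

    Raises ConfigError naming any unknown key or non-numeric value.
    """
    if path is None:
        return Config()
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid config syntax in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be an object, got {type(data).__name__}")
    known = set(Config.__dataclass_fields__)
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"config key {key!r} must be a number")
    return Config(**data)
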