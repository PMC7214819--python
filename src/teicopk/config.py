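"""YAML run configuration.

A config file may override cohort, design, estimation and simulation
defaults; unknown keys raise immediately with the offending path so typos
surface as schema diagnostics rather than silently ignored settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .dosing import RegimenSpec, TargetWindow
from .popmodel import ResidualSpec
from .synthetic_data import CohortSpec, StudyDesign

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Validated run settings used by the command-line interface."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    regimen: RegimenSpec = field(default_factory=RegimenSpec)
    residual: ResidualSpec = field(default_factory=ResidualSpec)
    window: TargetWindow = field(default_factory=TargetWindow)
    design: StudyDesign = field(default_factory=StudyDesign)
    seed: int = 20200505
    include_threshold: float = 3.84
    exclude_threshold: float = 6.64


def _build(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{path}' block: {exc}") from exc


def load_config(path: Optional[str] = None) -> RunConfig:
    """Load a :class:`RunConfig`, applying overrides from a YAML file."""
    config = RunConfig()
    if path is None:
        return config
    raw: Any = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    blocks = {
        "cohort": CohortSpec,
        "regimen": RegimenSpec,
        "residual": ResidualSpec,
        "window": TargetWindow,
    }
    updates: dict[str, Any] = {}
    for key, value in raw.items():
        if key in blocks:
            if not isinstance(value, dict):
                raise ConfigError(f"'{key}' must be a mapping")
            if key == "cohort" and "stratum_fractions" in value:
                value = dict(value, stratum_fractions=tuple(value["stratum_fractions"]))
            updates[key] = _build(blocks[key], value, key)
        elif key == "design":
            if not isinstance(value, dict):
                raise ConfigError("'design' must be a mapping")
            value = dict(value)
            if "regimen" in value:
                value["regimen"] = _build(RegimenSpec, value["regimen"], "design.regimen")
            if "n_samples_probs" in value:
                value["n_samples_probs"] = tuple(value["n_samples_probs"])
            updates["design"] = _build(StudyDesign, value, "design")
        elif key in ("seed", "include_threshold", "exclude_threshold"):
            updates[key] = value
        else:
            raise ConfigError(f"unknown top-level key '{key}'")
    return replace(config, **updates)
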