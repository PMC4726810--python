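"""Run configuration: YAML -> validated parameter sets.

Every field defaults to the published model value; unknown keys are rejected
with a field-level message so typos cannot silently fall back to defaults.
"""
from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Dict, Tuple

import yaml

from .params import (DiffusionParams, HeadGeometry, KineticsParams,
                     LatticeParams, ModelParams, ObstacleParams,
                     ParameterError, WLCParams)

_SECTIONS = {
    "wlc": WLCParams,
    "geometry": HeadGeometry,
    "lattice": LatticeParams,
    "diffusion": DiffusionParams,
    "obstacle": ObstacleParams,
    "kinetics": KineticsParams,
}
_SECTION_ATTR = {"wlc": "wlc", "geometry": "geom", "lattice": "lattice",
                 "diffusion": "diffusion", "obstacle": "obstacle",
                 "kinetics": "kinetics"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _build_section(cls, data: Dict[str, Any], section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    try:
        return cls(**coerced)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(f"invalid value in section '{section}': {exc}") from exc


def params_from_dict(data: Dict[str, Any]) -> Tuple[ModelParams, Dict[str, Any]]:
    """Build ModelParams from a nested dict; returns (params, extras).

    ``extras`` holds the run-level keys (seed, output, ...) that are not
    physical parameters.
    """
    data = dict(data or {})
    extras = {k: data.pop(k) for k in ("seed", "output", "run") if k in data}
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[_SECTION_ATTR[section]] = _build_section(
                cls, data[section] or {}, section)
    return ModelParams(**kwargs), extras


def load_config(path) -> Tuple[ModelParams, Dict[str, Any]]:
    """Load and validate a YAML run configuration."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return params_from_dict(data)


def params_to_dict(params: ModelParams) -> Dict[str, Any]:
    """Inverse of params_from_dict (round-trips every parameter)."""
    out = {}
    for section, attr in _SECTION_ATTR.items():
        d = dataclasses.asdict(getattr(params, attr))
        out[section] = {k: list(v) if isinstance(v, tuple) else v
                        for k, v in d.items()}
    return out
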