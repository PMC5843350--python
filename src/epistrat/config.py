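"""TOML configuration loading and validation.

A run is described by a structured text file with sections::

    [simulation]   variant, genotype, duration, seed, box, grid, ...
    [mechanics]    every MechanicsParams field
    [lifecycle]    every LifecycleParams field
    [lineage]      every OvolRegulation field (weights + pass-through rates)
    [feedback]     calcium-on-Ovol gains (Signal variant)
    [morphogen]    MorphogenGrid parameters

Absent fields take the package defaults; unknown keys are rejected with an
error naming the offender, and every parameter invariant is validated on
construction.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .lifecycle import LifecycleParams
from .lineage import OvolRegulation
from .mechanics import MechanicsParams
from .simulator import SignalFeedback, SimulationConfig

__all__ = ["ConfigError", "load_config"]

_SECTION_TYPES = {
    "mechanics": ("mech", MechanicsParams),
    "lifecycle": ("life", LifecycleParams),
    "lineage": ("reg", OvolRegulation),
    "feedback": ("feedback", SignalFeedback),
}

_SIM_FIELDS = {
    f.name for f in dataclasses.fields(SimulationConfig)
} - {"mech", "life", "reg", "feedback", "morphogen"}

_MORPHOGEN_KEYS = {
    "Ds_base", "ds_decay", "delta_s1", "delta_s2", "dt_pde", "n_substeps",
    "top_absorbing",
}


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _build(section: str, cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in [{section}]; allowed: {sorted(allowed)}"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid [{section}] parameters: {exc}") from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a TOML run configuration."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: not valid TOML: {exc}") from exc

    unknown_sections = set(doc) - set(_SECTION_TYPES) - {"simulation", "morphogen"}
    if unknown_sections:
        raise ConfigError(f"unknown section(s): {sorted(unknown_sections)}")

    kwargs: dict = {}
    sim = doc.get("simulation", {})
    unknown = set(sim) - _SIM_FIELDS
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in [simulation]; allowed: {sorted(_SIM_FIELDS)}"
        )
    kwargs.update(sim)
    if "box" in kwargs:
        kwargs["box"] = tuple(float(v) for v in kwargs["box"])

    for section, (attr, cls) in _SECTION_TYPES.items():
        if section in doc:
            kwargs[attr] = _build(section, cls, doc[section])

    if "morphogen" in doc:
        unknown = set(doc["morphogen"]) - _MORPHOGEN_KEYS
        if unknown:
            raise ConfigError(
                f"unknown key(s) {sorted(unknown)} in [morphogen]; "
                f"allowed: {sorted(_MORPHOGEN_KEYS)}"
            )
        kwargs["morphogen"] = dict(doc["morphogen"])

    try:
        return SimulationConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
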