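"""YAML configuration loading.

A config file may contain any of the sections ``model``, ``mapping``,
``simulation``, ``spectral`` and ``sweep``; each key overrides the
corresponding dataclass default.  Unknown keys are rejected so typos
fail loudly.

Example::

    model:
      mu_r: 86
      C1: 35
    mapping:
      S_max: 0.07
      S_min: 0.02
    simulation:
      duration: 30
      n_repeats: 20
      seed: 1
    spectral:
      band_low: 1
      band_high: 40
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .abeta import calibrate
from .errors import ConfigurationError
from .model import ModelParameters
from .simulation import SimulationConfig
from .spectral import SpectralConfig

__all__ = ["load_config", "RunConfig"]

_SECTIONS = ("model", "mapping", "simulation", "spectral", "sweep")
_MAPPING_KEYS = ("beta_off", "beta_max", "S_max", "S_min")


class RunConfig:
    """Bundle of the four layer configurations plus raw sweep options."""

    def __init__(self, model, mapping, simulation, spectral, sweep):
        self.model = model
        self.mapping = mapping
        self.simulation = simulation
        self.spectral = spectral
        self.sweep = sweep  # plain dict of sweep overrides, may be empty


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section '{name}'; "
            f"allowed: {sorted(allowed)}")
    return cls(**section)


def load_config(path=None, overrides=None) -> RunConfig:
    """Load a YAML config file, returning fully built configurations.

    ``overrides`` is an optional ``{section: {key: value}}`` mapping
    applied on top of the file (used by the CLI flags).
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must contain a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(
            f"unknown section(s) {sorted(unknown)}; allowed: {list(_SECTIONS)}")
    merged = {s: dict(raw.get(s) or {}) for s in _SECTIONS}
    for section, kv in (overrides or {}).items():
        merged.setdefault(section, {}).update(
            {k: v for k, v in kv.items() if v is not None})

    map_kwargs = merged["mapping"]
    bad = set(map_kwargs) - set(_MAPPING_KEYS)
    if bad:
        raise ConfigurationError(
            f"unknown key(s) {sorted(bad)} in section 'mapping'; "
            f"allowed: {list(_MAPPING_KEYS)}")
    mapping = calibrate(**map_kwargs)

    sim_kwargs = dict(merged["simulation"])
    model = _build(ModelParameters, merged["model"], "model")
    simulation = _build(SimulationConfig, sim_kwargs, "simulation")
    spec_kwargs = dict(merged["spectral"])
    spec_kwargs.setdefault("fs", simulation.fs)
    spectral = _build(SpectralConfig, spec_kwargs, "spectral")
    return RunConfig(model, mapping, simulation, spectral, merged["sweep"])
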