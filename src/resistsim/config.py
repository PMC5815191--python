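"""YAML scenario configuration.

A scenario document has two optional per-insecticide sections plus global
keys; anything omitted falls back to the base-scenario defaults, and unknown
keys are rejected rather than ignored::

    insecticide1:
      effectiveness: 0.8
      start_frequency: 0.01
    insecticide2:
      start_frequency: 0.01
    recombination_rate: 0.5     # default 0.5 (unlinked)
    resistance_threshold: 0.5   # default 0.5
    max_generations: 500        # default 500

A per-insecticide ``exposure`` key sets both sexes at once; explicit
``exposure_female`` / ``exposure_male`` keys override it.
"""

from __future__ import annotations

import logging
from dataclasses import fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .params import InsecticideParams, ParameterError
from .strategies import Scenario

logger = logging.getLogger(__name__)

_INSECTICIDE_KEYS = {f.name for f in fields(InsecticideParams)} | {"exposure"}
_GLOBAL_KEYS = {
    "insecticide1",
    "insecticide2",
    "recombination_rate",
    "resistance_threshold",
    "max_generations",
}
_SCENARIO_DEFAULTS = {
    "recombination_rate": 0.5,
    "resistance_threshold": 0.5,
    "max_generations": 500,
}


class ConfigError(ValueError):
    """The configuration document violates the scenario schema."""


def _parse_insecticide(section: Mapping[str, Any] | None, label: str) -> InsecticideParams:
    section = dict(section or {})
    unknown = set(section) - _INSECTICIDE_KEYS
    if unknown:
        raise ConfigError(
            f"{label}: unknown keys {sorted(unknown)}; "
            f"legal keys are {sorted(_INSECTICIDE_KEYS)}"
        )
    if "exposure" in section:
        both = section.pop("exposure")
        section.setdefault("exposure_female", both)
        section.setdefault("exposure_male", both)
    try:
        return InsecticideParams(**section)
    except ParameterError as exc:
        raise ConfigError(f"{label}: {exc}") from exc


def scenario_from_dict(doc: Mapping[str, Any]) -> Scenario:
    """Validate a parsed configuration mapping into a :class:`Scenario`."""
    if not isinstance(doc, Mapping):
        raise ConfigError(f"configuration must be a mapping, got {type(doc).__name__}")
    unknown = set(doc) - _GLOBAL_KEYS
    if unknown:
        raise ConfigError(
            f"unknown top-level keys {sorted(unknown)}; legal keys are {sorted(_GLOBAL_KEYS)}"
        )
    settings = dict(_SCENARIO_DEFAULTS)
    for key in _SCENARIO_DEFAULTS:
        if key in doc:
            settings[key] = doc[key]
        else:
            logger.info("config: %s not set, using default %r", key, settings[key])
    try:
        return Scenario(
            insecticide1=_parse_insecticide(doc.get("insecticide1"), "insecticide1"),
            insecticide2=_parse_insecticide(doc.get("insecticide2"), "insecticide2"),
            **settings,
        )
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc


def load_scenario(path: str | Path) -> Scenario:
    """Read and validate a YAML scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    return scenario_from_dict(doc)


def scenario_to_dict(scenario: Scenario) -> dict[str, Any]:
    """Round-trippable plain mapping for a scenario (YAML-serialisable)."""
    return {
        "insecticide1": {
            f.name: getattr(scenario.insecticide1, f.name)
            for f in fields(InsecticideParams)
        },
        "insecticide2": {
            f.name: getattr(scenario.insecticide2, f.name)
            for f in fields(InsecticideParams)
        },
        "recombination_rate": scenario.recombination_rate,
        "resistance_threshold": scenario.resistance_threshold,
        "max_generations": scenario.max_generations,
    }
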