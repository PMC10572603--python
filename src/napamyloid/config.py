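"""YAML/JSON run configuration: one file configures every pipeline stage."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InvalidConfigError
from .features import MarkingConfig
from .param_stats import StatsConfig
from .simulate import (
    AxonPopulationModel,
    DrugEffectModel,
    ExperimentDesign,
    StimulusProtocol,
)

__all__ = ["RunConfig", "load_run_config", "default_run_config", "config_hash"]

#: sections that must be present in a config file
REQUIRED_SECTIONS = ("design", "protocol", "population", "drug")
#: optional sections with defaults
OPTIONAL_SECTIONS = ("marking", "stats", "registration")


@dataclass(frozen=True)
class RegistrationConfig:
    zero_prefix: int = 10
    plateau_end: int = 100
    taper_tau: float = 20.0
    fit_segment: int = 1
    template_nerve: int | None = None
    ftol: float = 1e-10
    max_iter: int = 500


@dataclass(frozen=True)
class RunConfig:
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    population: AxonPopulationModel = field(default_factory=AxonPopulationModel)
    drug: DrugEffectModel = field(default_factory=DrugEffectModel)
    marking: MarkingConfig = field(default_factory=MarkingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)


_SECTION_TYPES = {
    "design": ExperimentDesign,
    "protocol": StimulusProtocol,
    "population": AxonPopulationModel,
    "drug": DrugEffectModel,
    "marking": MarkingConfig,
    "stats": StatsConfig,
    "registration": RegistrationConfig,
}


def _coerce(section: str, cls: type, data: Mapping[str, Any]) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise InvalidConfigError(
            f"unknown keys in section {section!r}: {sorted(unknown)}"
        )
    kwargs = dict(data)
    # YAML maps have string keys; integer-keyed maps need conversion
    if section == "design" and "conc_groups" in kwargs:
        kwargs["conc_groups"] = {
            int(k): (float(v[0]), int(v[1])) for k, v in kwargs["conc_groups"].items()
        }
    if section == "drug" and "effect_by_conc" in kwargs:
        kwargs["effect_by_conc"] = {
            int(k): float(v) for k, v in kwargs["effect_by_conc"].items()
        }
    for name in ("set0_currents", "set1_isis"):
        if name in kwargs:
            kwargs[name] = tuple(kwargs[name])
    return cls(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Every required section must be present; a missing one raises an
    :class:`InvalidConfigError` naming the section. Unknown keys are
    rejected rather than ignored.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise InvalidConfigError("config file must contain a mapping of sections")
    for section in REQUIRED_SECTIONS:
        if section not in raw:
            raise InvalidConfigError(f"config is missing required section {section!r}")
    unknown = set(raw) - set(REQUIRED_SECTIONS) - set(OPTIONAL_SECTIONS)
    if unknown:
        raise InvalidConfigError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTION_TYPES.items():
        data = raw.get(section)
        if data is None:
            continue
        if not isinstance(data, Mapping):
            raise InvalidConfigError(f"section {section!r} must be a mapping")
        kwargs[section] = _coerce(section, cls, data)
    return RunConfig(**kwargs)


def default_run_config() -> RunConfig:
    return RunConfig()


def config_as_dict(cfg: RunConfig) -> dict[str, Any]:
    def convert(obj: Any) -> Any:
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return {k: convert(getattr(cfg, k)) for k in _SECTION_TYPES}


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration, embedded in outputs."""
    blob = json.dumps(config_as_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
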