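"""YAML configuration: serialize/deserialize model and cohort settings.

A config file has up to four sections mirroring the module structure::

    pk:         {kaC: 144, kt: 28.8, ...}
    pd:         {kendoT4: 261, IC50: 0.024, ...}
    population: {beta_age: 0.464, omega_ic50: 0.77, ...}
    cohort:     {n_patients: 44, cmz_start_per_kg: 0.72, ...}

Any key absent from a section keeps its packaged default; the packaged default
config encodes the published parameter table verbatim.  Unknown keys are
rejected (listed by name) so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .cohort import CohortConfig
from .params import PDParameters, PKParameters, PopulationParameters
from .population import Severity


class ConfigError(ValueError):
    """Raised for unknown keys or malformed config values."""

    def __init__(self, message: str, offending_keys: list[str] | None = None):
        super().__init__(message)
        self.offending_keys = offending_keys or []


_SEVERITY_KEYED = {"age_dist", "ft4_dx_dist", "weight_median"}


def _fields(cls) -> dict[str, object]:
    return {f.name: f for f in dataclasses.fields(cls)}


def _build(cls, section: dict, section_name: str):
    known = _fields(cls)
    unknown = sorted(set(section) - set(known))
    if unknown:
        raise ConfigError(
            f"unknown keys in section {section_name!r}: {unknown}", unknown)
    kwargs = {}
    for key, value in section.items():
        if key in _SEVERITY_KEYED and isinstance(value, dict):
            value = {Severity(k): _tupled(v) for k, v in value.items()}
        elif isinstance(value, list):
            value = _tupled(value)
        kwargs[key] = value
    return cls(**kwargs)


def _tupled(v):
    if isinstance(v, list):
        return tuple(_tupled(x) for x in v)
    return v


def load_config(path) -> tuple[PopulationParameters, CohortConfig]:
    """Load a YAML config; missing sections/keys fall back to packaged defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = sorted(set(raw) - {"pk", "pd", "population", "cohort"})
    if unknown:
        raise ConfigError(f"unknown config sections: {unknown}", unknown)
    pk = _build(PKParameters, raw.get("pk", {}) or {}, "pk")
    pd_ = _build(PDParameters, raw.get("pd", {}) or {}, "pd")
    pop_section = dict(raw.get("population", {}) or {})
    nested = sorted(set(pop_section) & {"pd_pop", "pk_pop"})
    if nested:
        raise ConfigError(
            "structural parameters belong in the 'pd'/'pk' sections, "
            f"not under 'population': {nested}", nested)
    pop = _build(PopulationParameters,
                 pop_section | {"pd_pop": pd_, "pk_pop": pk}, "population")
    cohort = _build(CohortConfig, raw.get("cohort", {}) or {}, "cohort")
    return pop, cohort


def dump_config(pop: PopulationParameters, cohort: CohortConfig | None,
                path) -> None:
    """Write a complete config file for the given parameter objects."""
    def plain(obj, skip=()):
        out = {}
        for f in dataclasses.fields(obj):
            if f.name in skip:
                continue
            v = getattr(obj, f.name)
            if isinstance(v, dict):
                v = {(k.value if isinstance(k, Severity) else k): _listed(val)
                     for k, val in v.items()}
            else:
                v = _listed(v)
            out[f.name] = v
        return out

    doc = {
        "pk": plain(pop.pk_pop),
        "pd": plain(pop.pd_pop),
        "population": plain(pop, skip=("pd_pop", "pk_pop")),
    }
    if cohort is not None:
        doc["cohort"] = plain(cohort)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _listed(v):
    if isinstance(v, tuple):
        return [_listed(x) for x in v]
    return v


def default_config_path():
    """Path of the packaged default config (published parameter table)."""
    return resources.files("thyropmx").joinpath("data/default_config.yaml")


def load_default_config() -> tuple[PopulationParameters, CohortConfig]:
    with resources.as_file(default_config_path()) as p:
        return load_config(p)
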