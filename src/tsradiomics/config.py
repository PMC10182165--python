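"""Structured (YAML) run configuration.

One file drives every command: the stream schema (names and feature
columns), the model hyperparameters, the generator settings and the base
seed. Unknown keys are rejected so typos fail loudly, and every section is
optional — omitted values fall back to the package defaults (the study
layout and the tuned operating point).

Example::

    schema:
      streams:
        - {name: t2w, width: 17}
        - {name: adc, width: 27}
        - {name: psad, features: [psa_density]}
    hyperparams:
      epochs: 130
      learning_rate: 0.002
      dropout_rate: 0.2
      hidden_units: 16
    simulation:
      n_patients: 76
      n_progressors: 28
      drift_effect: 0.5
    seed: 0
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import yaml

from .cohort import StreamSchema
from .errors import ValidationError
from .lstm import TSRHyperparams
from .simulate import SimulationConfig

_TOP_KEYS = {"schema", "hyperparams", "simulation", "seed"}
_STREAM_KEYS = {"name", "width", "features"}


def load_config(path) -> dict:
    """Parse and validate a YAML config file; returns the raw mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config root must be a mapping, got {type(cfg).__name__}")
    unknown = set(cfg) - _TOP_KEYS
    if unknown:
        raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
    if "schema" in cfg:
        streams = (cfg["schema"] or {}).get("streams")
        if not streams:
            raise ValidationError("config key 'schema' must contain a 'streams' list")
        for s in streams:
            unknown = set(s) - _STREAM_KEYS
            if unknown:
                raise ValidationError(
                    f"unknown stream key(s) {sorted(unknown)} in stream {s.get('name')!r}"
                )
            if "name" not in s:
                raise ValidationError("every stream needs a 'name'")
            if ("width" in s) == ("features" in s):
                raise ValidationError(
                    f"stream {s['name']!r}: give exactly one of 'width' or 'features'"
                )
    for section, cls in (("hyperparams", TSRHyperparams), ("simulation", SimulationConfig)):
        if section in cfg and cfg[section]:
            valid = {f.name for f in dc_fields(cls)}
            unknown = set(cfg[section]) - valid
            if unknown:
                raise ValidationError(
                    f"unknown {section} key(s): {sorted(unknown)}"
                )
    return cfg


def schema_from_config(cfg: dict) -> StreamSchema:
    if "schema" not in cfg:
        return StreamSchema.default()
    streams = cfg["schema"]["streams"]
    names = tuple(s["name"] for s in streams)
    widths, feature_names = [], []
    for s in streams:
        if "features" in s:
            feats = tuple(str(f) for f in s["features"])
            widths.append(len(feats))
            feature_names.append(feats)
        else:
            widths.append(int(s["width"]))
            feature_names.append(tuple(f"{s['name']}_f{j}" for j in range(int(s["width"]))))
    return StreamSchema(stream_names=names, widths=tuple(widths),
                        feature_names=tuple(feature_names))


def hyper_from_config(cfg: dict) -> TSRHyperparams:
    section = dict(cfg.get("hyperparams") or {})
    if "hidden_units" in section and isinstance(section["hidden_units"], list):
        section["hidden_units"] = tuple(section["hidden_units"])
    return TSRHyperparams(**section)


def simulation_from_config(cfg: dict) -> SimulationConfig:
    section = dict(cfg.get("simulation") or {})
    schema = schema_from_config(cfg)
    section.setdefault("widths", schema.widths)
    section.setdefault("stream_names", schema.stream_names)
    if "seed" in cfg and "seed" not in section:
        section["seed"] = int(cfg["seed"])
    for key in ("widths", "stream_names", "gap_months", "drift_effect", "baseline_shift"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    return SimulationConfig(**section)
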