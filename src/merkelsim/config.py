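"""Configuration files: YAML with explicit unit strings.

Schema::

    preset: fig2            # optional, default "fig2"
    parameters:             # optional overrides
      g_BKCa: {value: 0.0, unit: "mS/cm^2"}
      ...
    switches:               # optional literal-equation switches
      literal_ip3r_h_equation: false
    scenarios: [fig4_highK, fig12_compression]   # optional subset to run

Unknown parameter keys are rejected; missing keys fall back to the preset
defaults with a logged notice.  All quantities carry a unit string which is
validated against the parameter's canonical unit and converted to SI at
load time.
"""
from __future__ import annotations

import logging
from pathlib import Path

import yaml

from .constants import from_si, to_si
from .errors import ConfigError
from .parameters import PARAM_TABLE, PRESETS, ModelParameters

logger = logging.getLogger(__name__)

_SWITCH_KEYS = ("literal_ip3r_h_equation", "literal_ip3_production",
                "literal_vesicle_synthesis")


def load_config(path: str | Path) -> tuple[ModelParameters, list[str]]:
    """Load a config file; returns (parameters, requested scenario names)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file does not parse: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    unknown_top = set(raw) - {"preset", "parameters", "switches", "scenarios"}
    if unknown_top:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown_top)}")

    preset = raw.get("preset", "fig2")
    if preset not in PRESETS:
        raise ConfigError(f"unknown preset {preset!r}; available: {PRESETS}")

    overrides: dict[str, float] = {}
    params_block = raw.get("parameters") or {}
    if not isinstance(params_block, dict):
        raise ConfigError("'parameters' must be a mapping")
    bad = sorted(set(params_block) - set(PARAM_TABLE))
    if bad:
        raise ConfigError(f"unknown parameter key(s): {bad}")
    for name, entry in params_block.items():
        canonical_unit = PARAM_TABLE[name][0]
        if isinstance(entry, dict):
            try:
                value = float(entry["value"])
            except (KeyError, TypeError, ValueError):
                raise ConfigError(f"parameter {name}: need a numeric 'value'")
            unit = entry.get("unit", canonical_unit)
            if unit != canonical_unit:
                raise ConfigError(
                    f"parameter {name}: unit {unit!r} does not match the "
                    f"canonical unit {canonical_unit!r}")
        else:
            try:
                value = float(entry)
            except (TypeError, ValueError):
                raise ConfigError(f"parameter {name}: not a number: {entry!r}")
            unit = canonical_unit
        overrides[name] = to_si(value, unit)

    switches = raw.get("switches") or {}
    bad_sw = sorted(set(switches) - set(_SWITCH_KEYS))
    if bad_sw:
        raise ConfigError(f"unknown switch key(s): {bad_sw}")

    missing = sorted(set(PARAM_TABLE) - set(overrides))
    if overrides and missing:
        logger.info("config overrides %d parameter(s); %d default(s) from "
                    "preset %r retained", len(overrides), len(missing), preset)
    try:
        params = ModelParameters.preset(preset, **overrides,
                                        **{k: bool(v) for k, v in switches.items()})
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    scenarios = raw.get("scenarios") or []
    if not isinstance(scenarios, list):
        raise ConfigError("'scenarios' must be a list of names")
    return params, [str(s) for s in scenarios]


def dump_parameters(params: ModelParameters) -> dict:
    """Serialisable mapping of every parameter in its canonical unit.

    Round-trips: feeding the result back through ``load_config`` reproduces
    the same SI values.
    """
    out = {}
    for name, (unit, *_defaults) in PARAM_TABLE.items():
        out[name] = {"value": from_si(params.values[name], unit), "unit": unit}
    return out
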