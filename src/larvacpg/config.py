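"""Flat key-value configuration files for networks, drives and runs.

The format is YAML restricted to a flat mapping (plus a ``drive`` list of
pulse mappings) whose keys mirror the reference parameter table: a, b, c,
d, e, f, tau_E, tau_I, tau_S, P_ext, b_E, b_I, b_S, theta_E, theta_I,
theta_S, and optionally alpha/beta/gamma (sensory feedback),
contralateral_kind/contralateral_weight (two-sided model), n_segments,
threshold, t_end and solver settings.  An ``include`` key pulls in a
packaged preset or another file; keys in the including file win.

``negate_inhibitory_weights: true`` accepts parameter files written in
the unsigned-magnitude convention (c, d, f given as positive numbers with
the inhibitory sign implied); the loader negates them, which yields
identical dynamics for the reference values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .integrator import SolverSettings
from .model_core import (
    ChainCoupling,
    ContralateralSpec,
    DriveProtocol,
    NetworkSpec,
    PopulationSpec,
    Pulse,
    SegmentCoupling,
    SensorySpec,
    SigmoidSpec,
    REFERENCE_PARAMS,
)

__all__ = ["load_config", "default_config", "build_network", "build_protocol", "PRESETS"]

_NETWORK_KEYS = set(REFERENCE_PARAMS) | {
    "alpha", "beta", "gamma",
    "contralateral_kind", "contralateral_weight",
    "n_segments", "negate_inhibitory_weights",
}
_RUN_KEYS = {
    "drive", "threshold", "t_end", "direction",
    "solver_method", "relative_tolerance", "absolute_tolerance",
    "max_step", "output_resolution", "seed", "experiment",
}

PRESETS = ("default", "fig3", "fig4", "fig5", "fig6", "fig7", "fig8", "fig10")


class ConfigError(ValueError):
    """Invalid or unknown configuration content, with the offending key."""


def _read_yaml(source: str | Path) -> dict[str, Any]:
    p = Path(source)
    if p.exists():
        text = p.read_text()
    elif str(source) in PRESETS:
        text = resources.files("larvacpg.presets").joinpath(f"{source}.yaml").read_text()
    else:
        raise ConfigError(f"no such config file or preset: {source!r}")
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config {source!r} must be a mapping")
    return data


def load_config(
    source: str | Path = "default", overrides: dict[str, Any] | None = None
) -> dict[str, Any]:
    """Resolve a config file/preset with includes and overrides applied."""
    data = _read_yaml(source)
    if "include" in data:
        base = load_config(data.pop("include"))
        base.update(data)
        data = base
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    for key in data:
        if key not in _NETWORK_KEYS | _RUN_KEYS:
            raise ConfigError(f"unknown configuration key: {key!r}")
    return data


def default_config() -> dict[str, Any]:
    return load_config("default")


def build_network(cfg: dict[str, Any]) -> NetworkSpec:
    """Validated NetworkSpec from a resolved configuration mapping."""
    p = {**REFERENCE_PARAMS, **{k: cfg[k] for k in REFERENCE_PARAMS if k in cfg}}
    if cfg.get("negate_inhibitory_weights"):
        for key in ("c", "d", "f"):
            p[key] = -abs(p[key])
    n = int(cfg.get("n_segments", 8))
    sensory = None
    if any(k in cfg for k in ("alpha", "beta", "gamma")):
        sensory = SensorySpec(
            float(cfg.get("alpha", 0.0)),
            float(cfg.get("beta", 0.0)),
            float(cfg.get("gamma", 0.0)),
            PopulationSpec(p["tau_S"], SigmoidSpec(p["b_S"], p["theta_S"])),
        )
    contralateral = None
    if "contralateral_kind" in cfg:
        if "contralateral_weight" not in cfg:
            raise ConfigError("contralateral_kind given without contralateral_weight")
        contralateral = ContralateralSpec(
            cfg["contralateral_kind"], float(cfg["contralateral_weight"])
        )
    try:
        return NetworkSpec(
            n_segments=n,
            excitatory=PopulationSpec.with_derived_ceiling(
                float(p["tau_E"]), SigmoidSpec(float(p["b_E"]), float(p["theta_E"]))
            ),
            inhibitory=PopulationSpec.with_derived_ceiling(
                float(p["tau_I"]), SigmoidSpec(float(p["b_I"]), float(p["theta_I"]))
            ),
            segment=SegmentCoupling(float(p["a"]), float(p["c"]), float(p["e"]), float(p["f"])),
            chain=ChainCoupling.uniform(float(p["b"]), float(p["d"]), n),
            sensory=sensory,
            contralateral=contralateral,
        )
    except ValueError as err:
        raise ConfigError(str(err)) from err


def build_protocol(cfg: dict[str, Any]) -> DriveProtocol:
    """DriveProtocol from the ``drive`` list (default: P_ext on the
    posterior segment for 2 t.u.)."""
    n = int(cfg.get("n_segments", 8))
    drive = cfg.get("drive")
    if drive is None:
        return DriveProtocol.single(n, float(cfg.get("P_ext", REFERENCE_PARAMS["P_ext"])))
    if not isinstance(drive, list):
        raise ConfigError("'drive' must be a list of pulse mappings")
    pulses = []
    for k, item in enumerate(drive):
        if not isinstance(item, dict):
            raise ConfigError(f"drive[{k}] must be a mapping")
        unknown = set(item) - {"segment", "strength", "onset", "duration", "side"}
        if unknown:
            raise ConfigError(f"drive[{k}] has unknown keys: {sorted(unknown)}")
        try:
            pulses.append(
                Pulse(
                    int(item.get("segment", n)),
                    float(item.get("strength", cfg.get("P_ext", REFERENCE_PARAMS["P_ext"]))),
                    float(item.get("onset", 0.0)),
                    float(item.get("duration", 2.0)),
                    item.get("side", "only"),
                )
            )
        except ValueError as err:
            raise ConfigError(f"drive[{k}]: {err}") from err
    return DriveProtocol(tuple(pulses))


def build_settings(cfg: dict[str, Any]) -> SolverSettings:
    kw = {}
    for cfg_key, field_name in (
        ("solver_method", "method"),
        ("relative_tolerance", "relative_tolerance"),
        ("absolute_tolerance", "absolute_tolerance"),
        ("max_step", "max_step"),
        ("output_resolution", "output_resolution"),
    ):
        if cfg_key in cfg:
            kw[field_name] = cfg[cfg_key]
    try:
        return SolverSettings(**kw)
    except ValueError as err:
        raise ConfigError(str(err)) from err
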