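"""Run configuration: schema-validated TOML with provenance tracking.

A run configuration selects the model (``abm`` or ``hydro``), its
parameter tables, the schedule (total time, snapshot interval), seed and
output paths.  Unknown keys are rejected; every parameter not present in
the user file is filled from the bundled default set and tagged with its
provenance ("paper" for values printed in the reference study, "repo
default" otherwise, "file" for user-supplied values), and the full tagged
table is echoed into output metadata.
"""

from __future__ import annotations

import importlib.resources
import tomllib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .signaling import ParameterError, SignalingParams
from .abm import ABMParams
from .hydro import HydroParams

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config",
           "abm_params_from_config", "hydro_params_from_config"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


_SCHEMA = {
    "abm": {"v0", "Gamma", "omega", "D_R", "r_p", "r_c", "L", "N", "dt", "M",
            "D_c", "w"},
    "hydro": {"v0", "D_rho", "sigma", "delta", "D_p", "chi", "omega", "D_c",
              "alpha", "beta", "epsilon", "a", "b", "M", "L", "rho0", "dt",
              "noise_amplitude", "theta_mode", "kappa", "dealias",
              "neg_policy", "neg_tol", "kernel_count", "kernel_amplitude"},
    "signaling": {"alpha", "beta", "epsilon", "a", "b"},
    "schedule": {"t_end", "snapshot_interval"},
    "output": {"path", "png_dir"},
    "analysis": {"clusters", "information"},
}
_TOP_KEYS = {"model", "seed"} | set(_SCHEMA)

# keys that must be non-negative / strictly positive, checked with names
_NONNEG = {"D_c", "D_R", "D_rho", "D_p", "alpha", "beta", "epsilon", "b",
           "Gamma", "omega", "noise_amplitude", "chi", "neg_tol"}
_POSITIVE = {"a", "delta", "dt", "t_end", "snapshot_interval", "L", "M", "N",
             "r_p", "r_c", "rho0", "kappa", "v0"}


@dataclass
class RunConfig:
    model: str
    seed: int
    abm: dict
    hydro: dict
    signaling: dict
    schedule: dict
    output: dict
    analysis: dict
    provenance: dict = dc_field(default_factory=dict)

    def section(self, name: str) -> dict:
        return getattr(self, name)

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "seed": self.seed,
            **{s: dict(getattr(self, s)) for s in _SCHEMA},
        }


def _defaults() -> dict:
    text = importlib.resources.files("commswarm").joinpath("defaults.toml").read_text()
    return tomllib.loads(text)


def _validate_numbers(section: str, table: dict) -> None:
    for key, val in table.items():
        if key in _NONNEG and isinstance(val, (int, float)) and val < 0:
            raise ConfigError(f"[{section}] {key} must be >= 0, got {val}")
        if key in _POSITIVE and isinstance(val, (int, float)) and val <= 0:
            raise ConfigError(f"[{section}] {key} must be > 0, got {val}")


def load_config(path) -> RunConfig:
    """Parse, validate and default-fill a TOML run configuration."""
    raw = tomllib.loads(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    defaults = _defaults()
    default_prov = defaults.pop("provenance", {})
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    model = raw.get("model", defaults["model"])
    if model not in ("abm", "hydro"):
        raise ConfigError(f"model must be 'abm' or 'hydro', got {model!r}")
    seed = raw.get("seed", defaults["seed"])
    sections = {}
    provenance = {
        "model": "file" if "model" in raw else "repo default",
        "seed": "file" if "seed" in raw else "repo default",
    }
    for name, allowed in _SCHEMA.items():
        user = raw.get(name, {})
        if not isinstance(user, dict):
            raise ConfigError(f"[{name}] must be a table")
        bad = set(user) - allowed
        if bad:
            raise ConfigError(f"unknown keys in [{name}]: {sorted(bad)}")
        merged = dict(defaults.get(name, {}))
        merged.update(user)
        _validate_numbers(name, merged)
        sections[name] = merged
        for key in merged:
            tag = "file" if key in user else default_prov.get(
                f"{name}.{key}", "repo default"
            )
            provenance[f"{name}.{key}"] = tag
    return RunConfig(
        model=model, seed=seed, provenance=provenance,
        **{name: sections.get(name, {}) for name in _SCHEMA},
    )


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    return repr(v)


def dump_config(cfg: RunConfig) -> str:
    """Serialize a configuration back to TOML (semantically round-trips)."""
    lines = [f"model = {_fmt(cfg.model)}", f"seed = {_fmt(cfg.seed)}", ""]
    for name in _SCHEMA:
        table = getattr(cfg, name)
        if not table:
            continue
        lines.append(f"[{name}]")
        for key, val in table.items():
            lines.append(f"{key} = {_fmt(val)}")
        lines.append("")
    return "\n".join(lines)


def abm_params_from_config(cfg: RunConfig) -> ABMParams:
    sig = SignalingParams(**cfg.signaling)
    return ABMParams(signaling=sig, **cfg.abm)


def hydro_params_from_config(cfg: RunConfig) -> HydroParams:
    keys = {"v0", "D_rho", "sigma", "delta", "D_p", "chi", "omega", "D_c",
            "alpha", "beta", "epsilon", "a", "b", "theta_mode", "kappa"}
    return HydroParams(**{k: v for k, v in cfg.hydro.items() if k in keys})
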