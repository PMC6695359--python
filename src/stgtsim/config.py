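"""Flat run configuration, YAML round-trip and the run manifest.

A run is fully described by a flat key-value mapping (preset name, seed,
population and protocol fields, agent parameters).  Configuration sources
compose as: preset defaults, then a config file, then explicit overrides —
later sources win.  The manifest written next to every run's outputs
records the resolved configuration, the seed and the package version, which
is sufficient to regenerate the outputs bit-for-bit.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, replace
from pathlib import Path

import yaml

from .agent import AgentParams
from .errors import ConfigurationError
from .experiment import (
    PopulationSpec,
    Preset,
    ProtocolConfig,
    format_omega_dist,
    parse_omega_dist,
    preset as get_preset,
)

__all__ = [
    "RunConfig",
    "load_config_file",
    "dump_config_file",
    "resolve_run_config",
    "write_manifest",
    "read_manifest",
]

_CONFIG_KEYS = (
    "preset",
    "seed",
    "n_subjects",
    "omega_dist",
    "omega_seed",
    "n_sessions",
    "trials_per_session",
    "task_variant",
    "feature_variant",
    "alpha",
    "gamma",
    "tau",
)


@dataclass(frozen=True)
class RunConfig:
    """A resolved, validated run configuration."""

    preset: str
    seed: int
    population: PopulationSpec
    protocol: ProtocolConfig
    params: AgentParams

    def as_flat_dict(self) -> dict:
        return {
            "preset": self.preset,
            "seed": self.seed,
            "n_subjects": self.population.n_subjects,
            "omega_dist": format_omega_dist(self.population.omega_dist),
            "omega_seed": self.population.omega_seed,
            "n_sessions": self.protocol.n_sessions,
            "trials_per_session": self.protocol.trials_per_session,
            "task_variant": self.protocol.task_variant,
            "feature_variant": self.protocol.feature_variant,
            "alpha": self.params.alpha,
            "gamma": self.params.gamma,
            "tau": self.params.tau,
        }


def load_config_file(path: str | Path) -> dict:
    """Read a flat YAML mapping; unknown keys are a configuration error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} is not a flat mapping")
    for key in data:
        if key not in _CONFIG_KEYS:
            raise ConfigurationError(f"unknown config key {key!r} in {path}")
    return data


def dump_config_file(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def resolve_run_config(
    preset_name: str,
    seed: int,
    file_config: dict | None = None,
    overrides: dict | None = None,
) -> RunConfig:
    """Compose preset defaults, config-file values and explicit overrides
    (in that order of increasing precedence) into a validated RunConfig."""
    p: Preset = get_preset(preset_name)
    merged: dict = {}
    for source in (file_config or {}, overrides or {}):
        for k, v in source.items():
            if k not in _CONFIG_KEYS:
                raise ConfigurationError(f"unknown config key {k!r}")
            if v is not None:
                merged[k] = v

    pop = p.population
    if "n_subjects" in merged:
        pop = replace(pop, n_subjects=int(merged["n_subjects"]))
    if "omega_dist" in merged:
        dist = merged["omega_dist"]
        if isinstance(dist, str):
            dist = parse_omega_dist(dist)
        pop = replace(pop, omega_dist=tuple(dist))
    if "omega_seed" in merged:
        pop = replace(pop, omega_seed=int(merged["omega_seed"]))

    proto = p.protocol
    for k in ("n_sessions", "trials_per_session"):
        if k in merged:
            proto = replace(proto, **{k: int(merged[k])})
    for k in ("task_variant", "feature_variant"):
        if k in merged:
            proto = replace(proto, **{k: str(merged[k])})

    params = AgentParams(
        alpha=float(merged.get("alpha", 0.03)),
        gamma=float(merged.get("gamma", 0.8)),
        tau=float(merged.get("tau", 0.15)),
    )
    seed = int(merged.get("seed", seed))
    return RunConfig(
        preset=preset_name, seed=seed, population=pop, protocol=proto, params=params
    )


def write_manifest(
    path: str | Path,
    run_config: RunConfig,
    version: str,
    outputs: list[str],
) -> None:
    manifest = {
        "version": version,
        "seed": run_config.seed,
        "preset": run_config.preset,
        "config": run_config.as_flat_dict(),
        "outputs": outputs,
        "created_at": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "config" not in data:
        raise ConfigurationError(f"{path} is not a run manifest")
    return data
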