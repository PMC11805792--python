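"""Run configuration: profiles, file loading (TOML/YAML) and round-tripping."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .errors import ConfigurationError
from .grid import ParameterGrid

#: Named scale profiles.  "paper" is the full-scale design; "desk" reproduces
#: the aggregate medians and percentages within Monte-Carlo error in minutes.
PROFILES: dict[str, dict[str, Any]] = {
    "paper": {"population_size": 1_000_000, "reps": 1000,
              "sample_sizes": (25, 50, 100, 250, 500, 1000)},
    "desk": {"population_size": 10_000, "reps": 100,
             "sample_sizes": (25, 100, 1000)},
}

_GRID_KEYS = {"noise_levels", "correlations", "beta1_values", "beta2_values",
              "beta3_values", "beta0", "mu_x", "mu_z", "sd_x", "sd_z"}
_CONFIG_KEYS = {"profile", "population_size", "reps", "sample_sizes", "alpha",
                "master_seed", "centering", "loocv", "grid"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a run (grid, scale, seed, options)."""

    grid: ParameterGrid = field(default_factory=ParameterGrid)
    population_size: int = 1_000_000
    reps: int = 1000
    sample_sizes: tuple[int, ...] = (25, 50, 100, 250, 500, 1000)
    alpha: float = 0.05
    master_seed: int = 0
    centering: bool = False
    loocv: bool = False

    def __post_init__(self):
        if self.reps < 1:
            raise ConfigurationError("reps must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha!r}")
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        object.__setattr__(self, "sample_sizes",
                           tuple(int(n) for n in self.sample_sizes))
        if len(self.sample_sizes) == 0:
            raise ConfigurationError("sample_sizes must be non-empty")
        for n in self.sample_sizes:
            if not (4 < n < self.population_size):
                raise ConfigurationError(
                    f"sample size {n} must satisfy 4 < n < population_size")


def config_to_dict(config: ExperimentConfig) -> dict[str, Any]:
    """Plain-data representation; inverse of ``config_from_dict``."""
    g = config.grid
    return {
        "population_size": config.population_size,
        "reps": config.reps,
        "sample_sizes": list(config.sample_sizes),
        "alpha": config.alpha,
        "master_seed": config.master_seed,
        "centering": config.centering,
        "loocv": config.loocv,
        "grid": {
            "noise_levels": list(g.noise_levels),
            "correlations": list(g.correlations),
            "beta1_values": list(g.beta1_values),
            "beta2_values": list(g.beta2_values),
            "beta3_values": list(g.beta3_values),
            "beta0": g.beta0,
            "mu_x": g.mu_x, "mu_z": g.mu_z, "sd_x": g.sd_x, "sd_z": g.sd_z,
        },
    }


def config_from_dict(raw: dict[str, Any],
                     profile: Optional[str] = None) -> ExperimentConfig:
    """Build a validated config from plain data, rejecting unknown keys.

    Precedence: explicit keys in ``raw`` > profile defaults > paper defaults.
    ``profile`` may also be given as a key inside ``raw``.
    """
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    raw = dict(raw)
    profile = raw.pop("profile", profile)
    base: dict[str, Any] = {}
    if profile is not None:
        if profile not in PROFILES:
            raise ConfigurationError(
                f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        base.update(PROFILES[profile])
    grid_raw = raw.pop("grid", None)
    base.update(raw)
    if grid_raw is not None:
        if not isinstance(grid_raw, dict):
            raise ConfigurationError("'grid' must be a mapping")
        unknown = set(grid_raw) - _GRID_KEYS
        if unknown:
            raise ConfigurationError(f"unknown grid key(s): {sorted(unknown)}")
        try:
            base["grid"] = ParameterGrid(**grid_raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
    try:
        return ExperimentConfig(**base)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def load_config(path: Optional[Union[str, Path]] = None,
                profile: Optional[str] = None) -> ExperimentConfig:
    """Load a TOML or YAML config file; an empty/absent file gives the defaults.

    The format is chosen by suffix (``.toml`` vs anything else = YAML).
    Unknown keys are rejected with a message naming the key.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        if path.suffix == ".toml":
            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw, profile=profile)


def write_config(config: ExperimentConfig, path: Union[str, Path]) -> Path:
    """Serialize a config as YAML such that ``load_config`` round-trips it."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)
    return path
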