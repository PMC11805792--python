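"""Simulation parameter space: enumeration, interaction-shape typology, analysis counts.

The default grid crosses four noise levels, four predictor correlations and a
quarter-step lattice of regression weights (zero excluded for the two simple
effects, included for the product term), for 4 * 4 * 8 * 8 * 9 = 9216 cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigurationError, DomainError

SHAPE_NONE = "none"
SHAPE_SYNERGISTIC = "synergistic"
SHAPE_BUFFERING = "buffering"
SHAPE_ANTAGONISTIC = "antagonistic"

#: Canonical presentation order for grouped tables.
SHAPE_ORDER = (SHAPE_SYNERGISTIC, SHAPE_ANTAGONISTIC, SHAPE_BUFFERING, SHAPE_NONE)

_BETA_STEPS = tuple(i * 0.25 for i in range(-4, 5))  # -1.0 .. 1.0 in steps of 0.25

DEFAULT_NOISE_LEVELS = (3.0, 1.53, 1.0, 0.65)
DEFAULT_CORRELATIONS = (0.75, 0.5, 0.25, 0.0001)
DEFAULT_BETA12_VALUES = tuple(v for v in _BETA_STEPS if v != 0.0)
DEFAULT_BETA3_VALUES = _BETA_STEPS


@dataclass(frozen=True)
class BetaConfig:
    """Generating regression weights: intercept, two simple effects, product term."""

    beta0: float
    beta1: float
    beta2: float
    beta3: float


@dataclass(frozen=True)
class ParameterGrid:
    """The crossed simulation design.

    ``beta1_values``/``beta2_values`` must exclude 0 (a null simple effect is
    not part of the design); ``beta3_values`` may include 0 (no interaction).
    Predictor SDs are fixed at 1 in the default study.
    """

    noise_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    correlations: tuple[float, ...] = DEFAULT_CORRELATIONS
    beta1_values: tuple[float, ...] = DEFAULT_BETA12_VALUES
    beta2_values: tuple[float, ...] = DEFAULT_BETA12_VALUES
    beta3_values: tuple[float, ...] = DEFAULT_BETA3_VALUES
    beta0: float = 0.0
    mu_x: float = 1.0
    mu_z: float = 2.0
    sd_x: float = 1.0
    sd_z: float = 1.0

    def __post_init__(self):
        for name in ("noise_levels", "correlations", "beta1_values",
                     "beta2_values", "beta3_values"):
            values = getattr(self, name)
            if len(values) == 0:
                raise ConfigurationError(f"grid dimension {name!r} is empty")
            object.__setattr__(self, name, tuple(float(v) for v in values))
        for name in ("beta1_values", "beta2_values"):
            if any(v == 0.0 for v in getattr(self, name)):
                raise ConfigurationError(f"0 is not allowed in {name!r}")
        if any(not (-1.0 < r < 1.0) for r in self.correlations):
            raise ConfigurationError("correlations must lie strictly in (-1, 1)")
        if any(lam < 0 for lam in self.noise_levels):
            raise ConfigurationError("noise levels must be non-negative")
        if self.sd_x <= 0 or self.sd_z <= 0:
            raise ConfigurationError("predictor SDs must be positive")

    @property
    def n_conditions(self) -> int:
        return (len(self.noise_levels) * len(self.correlations)
                * len(self.beta1_values) * len(self.beta2_values)
                * len(self.beta3_values))


@dataclass(frozen=True)
class Condition:
    """One grid cell: weights, noise level, predictor correlation and metadata."""

    betas: BetaConfig
    noise_level: float
    correlation: float
    shape: str
    cell_id: str
    index: int
    mu_x: float = 1.0
    mu_z: float = 2.0
    sd_x: float = 1.0
    sd_z: float = 1.0


def classify_shape(betas: BetaConfig) -> str:
    """Classify the interaction shape from the signs of (beta1, beta2, beta3).

    ``none`` when beta3 = 0; ``synergistic`` when all three share a sign;
    ``buffering`` when the simple effects oppose each other; ``antagonistic``
    when the simple effects share a sign opposed by the product term.
    Magnitudes never enter, so the label needs no designated moderator and is
    invariant to negating all three weights simultaneously.
    """
    if betas.beta1 == 0 or betas.beta2 == 0:
        raise DomainError("classify_shape requires beta1 != 0 and beta2 != 0")
    if betas.beta3 == 0:
        return SHAPE_NONE
    s1 = math.copysign(1.0, betas.beta1)
    s2 = math.copysign(1.0, betas.beta2)
    s3 = math.copysign(1.0, betas.beta3)
    if s1 == s2 == s3:
        return SHAPE_SYNERGISTIC
    if s1 != s2:
        return SHAPE_BUFFERING
    return SHAPE_ANTAGONISTIC


def _cell_id(noise_level: float, correlation: float,
             b1: float, b2: float, b3: float) -> str:
    return (f"lam{noise_level:g}_r{correlation:g}"
            f"_b1{b1:+g}_b2{b2:+g}_b3{b3:+g}")


def enumerate_conditions(grid: ParameterGrid) -> list[Condition]:
    """All grid cells in a fixed deterministic order.

    Ordering is lexicographic over (noise level desc, correlation desc,
    beta1 asc, beta2 asc, beta3 asc); indices and cell ids are stable under
    re-enumeration of the same grid.
    """
    conditions: list[Condition] = []
    index = 0
    for lam in sorted(grid.noise_levels, reverse=True):
        for r in sorted(grid.correlations, reverse=True):
            for b1 in sorted(grid.beta1_values):
                for b2 in sorted(grid.beta2_values):
                    for b3 in sorted(grid.beta3_values):
                        betas = BetaConfig(grid.beta0, b1, b2, b3)
                        conditions.append(Condition(
                            betas=betas,
                            noise_level=lam,
                            correlation=r,
                            shape=classify_shape(betas),
                            cell_id=_cell_id(lam, r, b1, b2, b3),
                            index=index,
                            mu_x=grid.mu_x, mu_z=grid.mu_z,
                            sd_x=grid.sd_x, sd_z=grid.sd_z,
                        ))
                        index += 1
    return conditions


def _shape_cell_counts(grid: ParameterGrid) -> dict[str, int]:
    # Pure sign combinatorics over the value lists -- no enumeration, so this
    # stays an independent route from enumerate_conditions.
    p1 = sum(v > 0 for v in grid.beta1_values)
    m1 = len(grid.beta1_values) - p1
    p2 = sum(v > 0 for v in grid.beta2_values)
    m2 = len(grid.beta2_values) - p2
    p3 = sum(v > 0 for v in grid.beta3_values)
    m3 = sum(v < 0 for v in grid.beta3_values)
    z3 = len(grid.beta3_values) - p3 - m3
    return {
        SHAPE_SYNERGISTIC: p1 * p2 * p3 + m1 * m2 * m3,
        SHAPE_ANTAGONISTIC: p1 * p2 * m3 + m1 * m2 * p3,
        SHAPE_BUFFERING: (p1 * m2 + m1 * p2) * (p3 + m3),
        SHAPE_NONE: len(grid.beta1_values) * len(grid.beta2_values) * z3,
    }


def count_analyses(grid: ParameterGrid, reps: int, sample_sizes: Sequence[int],
                   group_by: str = "shape_noise") -> pd.DataFrame:
    """Exact analysis counts ``k`` per group -- combinatorics, no simulation.

    ``group_by`` is one of ``"shape"`` (per shape, all conditions),
    ``"shape_noise"`` (per shape per noise level, summed over sample sizes)
    or ``"shape_n"`` (per shape per sample size, summed over noise levels).
    """
    if reps <= 0:
        raise ConfigurationError("reps must be positive")
    if len(sample_sizes) == 0:
        raise ConfigurationError("sample_sizes must be non-empty")
    per_shape = _shape_cell_counts(grid)
    n_corr = len(grid.correlations)
    n_noise = len(grid.noise_levels)
    rows = []
    if group_by == "shape":
        for shape in SHAPE_ORDER:
            k = per_shape[shape] * n_corr * n_noise * reps * len(sample_sizes)
            rows.append({"shape": shape, "k": k})
    elif group_by == "shape_noise":
        for shape in SHAPE_ORDER:
            for lam in sorted(grid.noise_levels):
                k = per_shape[shape] * n_corr * reps * len(sample_sizes)
                rows.append({"shape": shape, "noise_level": lam, "k": k})
    elif group_by == "shape_n":
        for shape in SHAPE_ORDER:
            for n in sorted(sample_sizes):
                k = per_shape[shape] * n_corr * n_noise * reps
                rows.append({"shape": shape, "n": int(n), "k": k})
    else:
        raise ConfigurationError(
            f"group_by must be 'shape', 'shape_noise' or 'shape_n', got {group_by!r}")
    return pd.DataFrame(rows)


def conditions_frame(conditions: Iterable[Condition]) -> pd.DataFrame:
    """Tidy export of an enumeration (CSV-ready)."""
    return pd.DataFrame([
        {
            "cell_id": c.cell_id,
            "index": c.index,
            "lambda": c.noise_level,
            "r": c.correlation,
            "beta0": c.betas.beta0,
            "beta1": c.betas.beta1,
            "beta2": c.betas.beta2,
            "beta3": c.betas.beta3,
            "shape": c.shape,
        }
        for c in conditions
    ])
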