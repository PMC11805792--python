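"""Synthetic finite populations and repeated sampling.

Predictors are bivariate normal; the outcome is a linear model with a product
term plus Gaussian noise whose SD is a multiple ``lambda`` of the realized SD
of the noiseless outcome.  The noise multiplier calibrates the population
R-squared of the correctly specified model to 1 / (1 + lambda^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .errors import DomainError
from .grid import BetaConfig

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def noise_from_r2(target_r2: float) -> float:
    """Noise multiplier lambda that calibrates the population R-squared.

    lambda = sqrt(1 / R^2 - 1), so that signal variance over total variance
    equals ``target_r2`` when the error SD is lambda times the signal SD.
    """
    if not (0.0 < target_r2 <= 1.0):
        raise DomainError(f"target_r2 must be in (0, 1], got {target_r2!r}")
    return math.sqrt(1.0 / target_r2 - 1.0)


def r2_from_noise(noise_level: float) -> float:
    """Inverse calibration: population R-squared implied by a noise multiplier."""
    if noise_level < 0:
        raise DomainError(f"noise_level must be >= 0, got {noise_level!r}")
    return 1.0 / (1.0 + noise_level ** 2)


@dataclass(frozen=True)
class PopulationSpec:
    """Generating parameters for one finite population."""

    betas: BetaConfig
    correlation: float
    noise_level: float
    size: int
    mu_x: float = 1.0
    mu_z: float = 2.0
    sd_x: float = 1.0
    sd_z: float = 1.0
    cell_id: Optional[str] = None

    def __post_init__(self):
        params = (self.betas.beta0, self.betas.beta1, self.betas.beta2,
                  self.betas.beta3, self.correlation, self.noise_level,
                  self.mu_x, self.mu_z, self.sd_x, self.sd_z)
        if not all(math.isfinite(p) for p in params):
            raise DomainError("population parameters must all be finite")
        if not (-1.0 < self.correlation < 1.0):
            raise DomainError(f"|correlation| must be < 1, got {self.correlation!r}")
        if self.noise_level < 0:
            raise DomainError("noise_level must be >= 0")
        if self.size < 2:
            raise DomainError("population size must be >= 2")
        if self.sd_x <= 0 or self.sd_z <= 0:
            raise DomainError("predictor SDs must be positive")


@dataclass
class Population:
    """A realized finite population (treated as ground truth for sampling)."""

    x: np.ndarray
    z: np.ndarray
    y_star: np.ndarray
    y: np.ndarray
    realized_sd_ystar: float
    spec: PopulationSpec

    @property
    def size(self) -> int:
        return self.x.shape[0]

    def realized_moments(self) -> dict[str, float]:
        """Means, SDs and correlation of the realized arrays (finite-population, ddof=0)."""
        return {
            "mean_x": float(self.x.mean()),
            "mean_z": float(self.z.mean()),
            "mean_y": float(self.y.mean()),
            "sd_x": float(self.x.std()),
            "sd_z": float(self.z.std()),
            "sd_y": float(self.y.std()),
            "sd_ystar": float(self.realized_sd_ystar),
            "corr_xz": float(np.corrcoef(self.x, self.z)[0, 1]),
        }


@dataclass
class Sample:
    """A simple random sample (without replacement) from a parent population."""

    x: np.ndarray
    z: np.ndarray
    y: np.ndarray
    n: int
    parent_cell_id: Optional[str] = None
    replicate_index: Optional[int] = None


def generate_population(spec: PopulationSpec, seed: SeedLike) -> Population:
    """Generate one finite population under ``spec``, deterministically from ``seed``.

    X is drawn first; Z is built from X by the conditional-normal construction
    Z = mu_z + sd_z * (r * (X - mu_x)/sd_x + sqrt(1 - r^2) * W), W ~ N(0, 1),
    giving the exact bivariate normal joint.  The error SD is the noise level
    times the *realized* SD of the noiseless outcome, so the signal-to-noise
    calibration holds for this population, not just in expectation.
    """
    rng = np.random.default_rng(seed)
    b = spec.betas
    u = rng.standard_normal(spec.size)
    w = rng.standard_normal(spec.size)
    r = spec.correlation
    x = spec.mu_x + spec.sd_x * u
    z = spec.mu_z + spec.sd_z * (r * u + math.sqrt(1.0 - r * r) * w)
    y_star = b.beta0 + b.beta1 * x + b.beta2 * z + b.beta3 * x * z
    sd_ystar = float(y_star.std())
    eps = rng.standard_normal(spec.size) * (spec.noise_level * sd_ystar)
    return Population(x=x, z=z, y_star=y_star, y=y_star + eps,
                      realized_sd_ystar=sd_ystar, spec=spec)


def draw_sample(population: Population, n: int, rng_state: SeedLike,
                replicate_index: Optional[int] = None) -> Sample:
    """Simple random sample of size ``n`` without replacement.

    Deterministic given ``rng_state``; n must exceed 2 (and downstream model
    fitting additionally requires n > number of coefficients).
    """
    if not (2 < n <= population.size):
        raise DomainError(
            f"sample size must satisfy 2 < n <= population size, got n={n}")
    rng = np.random.default_rng(rng_state)
    idx = rng.choice(population.size, size=n, replace=False)
    return Sample(x=population.x[idx], z=population.z[idx], y=population.y[idx],
                  n=n, parent_cell_id=population.spec.cell_id,
                  replicate_index=replicate_index)
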