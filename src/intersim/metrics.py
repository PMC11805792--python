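"""Effect-size and generalizability metrics.

R2(s) is the ordinary in-sample R-squared; R2(p) re-scores the same fitted
coefficients against the full parent population (variance explained about the
*population* mean of y, so the mean predictor scores exactly 0 and bad models
can go negative).  Overfit is R2(s) - R2(p); contrasts difference the two
models replicate by replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DomainError
from .ols import FitResult, ModelKind, design_matrix
from .population import Population


def f_squared(r2_full: float, r2_reduced: float) -> float:
    """Cohen's incremental effect size (R2_full - R2_reduced) / (1 - R2_full)."""
    if r2_full >= 1.0:
        raise DomainError("f_squared undefined at r2_full = 1")
    if r2_reduced > r2_full:
        raise DomainError("r2_reduced must not exceed r2_full")
    if r2_reduced < 0.0:
        raise DomainError("r2_reduced must be >= 0")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def rmse_star(r2: float) -> float:
    """RMSE normalized by SD(y): sqrt(1 - R2)."""
    if r2 > 1.0:
        raise DomainError(f"r2 must be <= 1, got {r2!r}")
    return math.sqrt(1.0 - r2)


def r2_population(coefficients: np.ndarray, model: ModelKind,
                  population: Population,
                  centering_means: Optional[tuple[float, float]] = None) -> float:
    """Score fitted coefficients against the full population.

    Predictions use the model's design over the population's x and z (with
    the original sample's centering offsets when the fit was centered); the
    result is 1 - SSE/SST with SST about the population mean of y, not
    clamped below at 0.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (model.n_coef,):
        raise DomainError(
            f"{model.kind} model expects {model.n_coef} coefficients, "
            f"got shape {coefficients.shape}")
    if model.centering and centering_means is None:
        raise DomainError("centered fits need centering_means to predict on a population")
    design = design_matrix(population.x, population.z, model, centering_means)
    y = population.y
    resid = y - design @ coefficients
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("degenerate population: y has zero variance")
    return 1.0 - float(resid @ resid) / sst


@dataclass
class GeneralizationRecord:
    """Sample fit quality vs. population generalization for one fitted model."""

    r2_s: float
    r2_p: float
    overfit: float  # r2_s - r2_p
    model: ModelKind
    cell_id: Optional[str]
    replicate: Optional[int]
    n: int


@dataclass
class ModelContrast:
    """Interaction-minus-simple differences of the three R-squared measures."""

    delta_r2_s: float
    delta_r2_p: float
    delta_overfit: float


def generalization_record(fit: FitResult, population: Population,
                          cell_id: Optional[str] = None,
                          replicate: Optional[int] = None) -> GeneralizationRecord:
    """Build the per-replicate generalization row for one fit."""
    r2_p = r2_population(fit.coefficients, fit.model, population,
                         fit.centering_means)
    if cell_id is None:
        cell_id = fit.sample_key[0]
    if replicate is None:
        replicate = fit.sample_key[1]
    return GeneralizationRecord(
        r2_s=fit.r2_sample, r2_p=r2_p, overfit=fit.r2_sample - r2_p,
        model=fit.model, cell_id=cell_id, replicate=replicate, n=fit.n)


def contrast(rec_simple: GeneralizationRecord,
             rec_interaction: GeneralizationRecord) -> ModelContrast:
    """Difference the two models' records from the same (cell, replicate, n)."""
    if rec_simple.model.kind != "simple" or rec_interaction.model.kind != "interaction":
        raise DomainError("contrast expects (simple record, interaction record)")
    key_s = (rec_simple.cell_id, rec_simple.replicate, rec_simple.n)
    key_i = (rec_interaction.cell_id, rec_interaction.replicate, rec_interaction.n)
    if key_s != key_i:
        raise DomainError(f"mismatched records: {key_s} vs {key_i}")
    return ModelContrast(
        delta_r2_s=rec_interaction.r2_s - rec_simple.r2_s,
        delta_r2_p=rec_interaction.r2_p - rec_simple.r2_p,
        delta_overfit=rec_interaction.overfit - rec_simple.overfit,
    )
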