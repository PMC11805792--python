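"""Closed-form consequences of omitting the product term.

When the simple-effects model is fit to data generated with a product term,
the population-level (and statistically expected) coefficients are

    b_e0 = beta0 - beta3 * mu_z * mu_x + beta3 * r
    b_e1 = beta1 + beta3 * mu_z
    b_e2 = beta2 + beta3 * mu_x

valid for unit predictor SDs (so that cov(X, Z) = r).  The residual of the
misspecified model inherits structure from the omitted term; this module also
quantifies that structure (error/XZ dependence and heteroscedasticity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .grid import Condition
from .population import Population, PopulationSpec


@dataclass(frozen=True)
class ExpectedEstimates:
    """Expected misspecified coefficients and their biases (b_en - beta_n)."""

    b_e0: float
    b_e1: float
    b_e2: float
    bias_0: float
    bias_1: float
    bias_2: float
    #: (b_e1 == 0, b_e2 == 0), by exact comparison (grid betas are exact quarters)
    cancellation_flags: tuple[bool, bool]
    #: (sign(b_e1) opposite to beta1, sign(b_e2) opposite to beta2)
    sign_flip_flags: tuple[bool, bool]


@dataclass
class ResidualDecomposition:
    """Structure of the misspecified model's error term.

    ``a, b, c`` are the population least-squares coefficients of the omitted
    component (beta3*X*Z + eps) on (1, X, Z); ``residual_series`` is what
    remains.  ``dependence_index`` is |corr(residual, X*Z)| and
    ``heteroscedasticity_index`` the residual-variance ratio between the top
    and bottom quartile of X*Z; their well-behaved (null) values are 0 and 1.
    """

    a: float
    b: float
    c: float
    residual_series: np.ndarray
    heteroscedasticity_index: float
    dependence_index: float


def expected_misspecified(spec: PopulationSpec) -> ExpectedEstimates:
    """Expected simple-effects coefficients under the generating ``spec``.

    Restricted to unit predictor SDs: the intercept formula uses the
    correlation where the covariance of X and Z belongs, and the two
    coincide only when sd_x = sd_z = 1.
    """
    if spec.sd_x != 1.0 or spec.sd_z != 1.0:
        raise ConfigurationError(
            "expected_misspecified requires unit predictor SDs "
            f"(got sd_x={spec.sd_x}, sd_z={spec.sd_z})")
    b = spec.betas
    b_e0 = b.beta0 - b.beta3 * spec.mu_z * spec.mu_x + b.beta3 * spec.correlation
    b_e1 = b.beta1 + b.beta3 * spec.mu_z
    b_e2 = b.beta2 + b.beta3 * spec.mu_x
    return ExpectedEstimates(
        b_e0=b_e0, b_e1=b_e1, b_e2=b_e2,
        bias_0=b_e0 - b.beta0, bias_1=b_e1 - b.beta1, bias_2=b_e2 - b.beta2,
        cancellation_flags=(b_e1 == 0.0, b_e2 == 0.0),
        sign_flip_flags=(b_e1 * b.beta1 < 0.0, b_e2 * b.beta2 < 0.0),
    )


@dataclass(frozen=True)
class TippingPoints:
    """Product-term values at which an expected simple effect is exactly 0."""

    beta3_for_b1: Optional[float]
    beta3_for_b2: Optional[float]


def tipping_points(spec: PopulationSpec) -> TippingPoints:
    """beta3 values cancelling b_e1 (= -beta1/mu_z) and b_e2 (= -beta2/mu_x).

    A zero predictor mean removes the corresponding root (the expected
    coefficient is then unbiased for every beta3); reported as None.
    """
    b = spec.betas
    b1_root = None if spec.mu_z == 0 else -b.beta1 / spec.mu_z
    b2_root = None if spec.mu_x == 0 else -b.beta2 / spec.mu_x
    return TippingPoints(beta3_for_b1=b1_root, beta3_for_b2=b2_root)


def residual_structure(population: Population,
                       spec: Optional[PopulationSpec] = None) -> ResidualDecomposition:
    """Decompose the omitted component beta3*X*Z + eps over a population.

    Regresses it on (1, X, Z) and reports how far the leftover residual is
    from well-behaved noise.  As the noise level grows, eps dominates and
    both indices approach their null values.
    """
    spec = spec or population.spec
    x, z = population.x, population.z
    eps = population.y - population.y_star
    xz = x * z
    target = spec.betas.beta3 * xz + eps
    design = np.column_stack((np.ones_like(x), x, z))
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    if resid.std() == 0.0:
        dep = 0.0
    else:
        dep = float(abs(np.corrcoef(resid, xz)[0, 1]))
    q1, q3 = np.quantile(xz, [0.25, 0.75])
    lo = resid[xz <= q1]
    hi = resid[xz >= q3]
    lo_var, hi_var = float(lo.var()), float(hi.var())
    if lo_var == 0.0:
        het = 1.0 if hi_var == 0.0 else float("inf")
    else:
        het = hi_var / lo_var
    return ResidualDecomposition(
        a=float(coef[0]), b=float(coef[1]), c=float(coef[2]),
        residual_series=resid, heteroscedasticity_index=het,
        dependence_index=dep)


def bias_table(conditions: Iterable[Condition]) -> pd.DataFrame:
    """Expected-estimate table for a grid slice (one row per condition)."""
    rows = []
    for c in conditions:
        spec = PopulationSpec(betas=c.betas, correlation=c.correlation,
                              noise_level=c.noise_level, size=2,
                              mu_x=c.mu_x, mu_z=c.mu_z,
                              sd_x=c.sd_x, sd_z=c.sd_z, cell_id=c.cell_id)
        ee = expected_misspecified(spec)
        rows.append({
            "cell_id": c.cell_id, "lambda": c.noise_level, "r": c.correlation,
            "beta0": c.betas.beta0, "beta1": c.betas.beta1,
            "beta2": c.betas.beta2, "beta3": c.betas.beta3,
            "b_e0": ee.b_e0, "b_e1": ee.b_e1, "b_e2": ee.b_e2,
            "bias_0": ee.bias_0, "bias_1": ee.bias_1, "bias_2": ee.bias_2,
            "b_e1_cancelled": ee.cancellation_flags[0],
            "b_e2_cancelled": ee.cancellation_flags[1],
            "b_e1_sign_flip": ee.sign_flip_flags[0],
            "b_e2_sign_flip": ee.sign_flip_flags[1],
        })
    return pd.DataFrame(rows)
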