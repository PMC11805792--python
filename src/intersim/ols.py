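"""Ordinary least squares for the two competing models.

The "simple" model regresses the outcome on an intercept, X and Z; the
"interaction" model adds the product term X*Z.  Fits use a QR factorization
of the design matrix (never explicit normal-equation inversion), classical
standard errors and two-sided t-based p values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

from .errors import DomainError, SingularDesignError
from .population import Sample

_RCOND = 1e-12


@dataclass(frozen=True)
class ModelKind:
    """Which design to fit, and whether to mean-center before the product."""

    kind: str  # "simple" | "interaction"
    centering: bool = False

    def __post_init__(self):
        if self.kind not in ("simple", "interaction"):
            raise DomainError(f"unknown model kind {self.kind!r}")

    @property
    def n_coef(self) -> int:
        return 4 if self.kind == "interaction" else 3

    @property
    def coef_names(self) -> tuple[str, ...]:
        return ("b0", "b1", "b2", "b3")[: self.n_coef]


SIMPLE = ModelKind("simple")
INTERACTION = ModelKind("interaction")
SIMPLE_CENTERED = ModelKind("simple", centering=True)
INTERACTION_CENTERED = ModelKind("interaction", centering=True)


def design_matrix(x: np.ndarray, z: np.ndarray, model: ModelKind,
                  centering_means: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Design matrix columns (1, x, z[, x*z]), optionally mean-centered.

    For a centered model, ``centering_means`` supplies the offsets; they
    default to the means of ``x`` and ``z`` themselves (the fitting case).
    Pass the *sample* means when predicting on other data.
    """
    if model.centering:
        if centering_means is None:
            centering_means = (float(x.mean()), float(z.mean()))
        x = x - centering_means[0]
        z = z - centering_means[1]
    cols = [np.ones_like(x), x, z]
    if model.kind == "interaction":
        cols.append(x * z)
    return np.column_stack(cols)


@dataclass
class FitResult:
    """OLS estimates for one model on one sample."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    r2_sample: float
    n: int
    model: ModelKind
    df_resid: int
    sse: float
    sst: float
    centering_means: Optional[tuple[float, float]]
    sample_key: tuple


def _sample_key(sample: Sample) -> tuple:
    # Lightweight fingerprint used to refuse cross-sample comparisons.
    return (sample.parent_cell_id, sample.replicate_index, sample.n,
            float(sample.x.sum()), float(sample.y.sum()))


def _qr_solve(design: np.ndarray, y: np.ndarray,
              context: dict | None = None):
    """Coefficients, classical SEs and error sums via reduced QR.

    Returns (coef, se, sse, df_resid).  Raises SingularDesignError when the
    design is numerically rank-deficient.
    """
    n, p = design.shape
    if n <= p:
        raise DomainError(f"need n > {p} observations to fit, got n={n}")
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    if diag.min() <= _RCOND * max(diag.max(), 1.0):
        ctx = context or {}
        raise SingularDesignError(
            "rank-deficient design matrix", cell_id=ctx.get("cell_id"),
            replicate=ctx.get("replicate"), n=n)
    c = q.T @ y
    coef = solve_triangular(r, c)
    resid = y - design @ coef
    sse = float(resid @ resid)
    df_resid = n - p
    sigma2 = sse / df_resid
    r_inv = solve_triangular(r, np.eye(p))
    se = np.sqrt(sigma2 * np.einsum("ij,ij->i", r_inv, r_inv))
    return coef, se, sse, df_resid


def fit_ols(sample: Sample, model: ModelKind) -> FitResult:
    """Fit one model to one sample by least squares.

    p values are two-sided from the t distribution with n - p degrees of
    freedom; R-squared is 1 - SSE/SST with SST about the sample mean of y.
    """
    centering_means = (
        (float(sample.x.mean()), float(sample.z.mean())) if model.centering else None)
    design = design_matrix(sample.x, sample.z, model, centering_means)
    context = {"cell_id": sample.parent_cell_id,
               "replicate": sample.replicate_index}
    coef, se, sse, df_resid = _qr_solve(design, sample.y, context)
    tstat = coef / se
    p_values = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    y = sample.y
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return FitResult(
        coefficients=coef, standard_errors=se, p_values=p_values,
        r2_sample=float(r2), n=sample.n, model=model, df_resid=df_resid,
        sse=sse, sst=sst, centering_means=centering_means,
        sample_key=_sample_key(sample))


def compare_centered(sample: Sample) -> dict[str, float]:
    """Fit the interaction model centered and uncentered and report the overlap.

    The product-term coefficient, its SE and the model R-squared are invariant
    to mean-centering; the intercept and simple-effect rows are not.
    """
    fit_u = fit_ols(sample, INTERACTION)
    fit_c = fit_ols(sample, INTERACTION_CENTERED)
    return {
        "b3_uncentered": float(fit_u.coefficients[3]),
        "b3_centered": float(fit_c.coefficients[3]),
        "se_b3_uncentered": float(fit_u.standard_errors[3]),
        "se_b3_centered": float(fit_c.standard_errors[3]),
        "r2_uncentered": fit_u.r2_sample,
        "r2_centered": fit_c.r2_sample,
    }


def r2_change(fit_simple: FitResult, fit_interaction: FitResult) -> float:
    """R2(s) of the interaction model minus the simple model, on one sample.

    Non-negative by model nesting; sub-epsilon negative values from floating
    point are clamped to exactly 0.
    """
    if fit_simple.model.kind != "simple" or fit_interaction.model.kind != "interaction":
        raise DomainError("r2_change expects (simple fit, interaction fit)")
    if fit_simple.sample_key != fit_interaction.sample_key:
        raise DomainError("fits come from different samples")
    delta = fit_interaction.r2_sample - fit_simple.r2_sample
    if -1e-10 < delta < 0.0:
        delta = 0.0
    return delta
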