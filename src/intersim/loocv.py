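"""Leave-one-out cross-validated R-squared (PRESS form).

The practical stand-in for population generalizability when no population is
available: r2_cv = 1 - PRESS/SST, with PRESS computed through the closed-form
leave-one-out identity e_i / (1 - h_ii) rather than n refits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .ols import ModelKind, _qr_solve, design_matrix
from .population import Sample

_LEVERAGE_TOL = 1e-10


@dataclass
class LoocvResult:
    r2_cv: float
    press: float
    leverages: np.ndarray


def loocv_r2(sample: Sample, model: ModelKind) -> LoocvResult:
    """Closed-form leave-one-out cross-validated R-squared for one fit.

    Equals the brute-force n-refit LOOCV to numerical precision.  SST is
    taken about the full-sample mean of y (standard PRESS-R2 convention),
    which makes r2_cv <= R2(s) provable: each LOO residual is the ordinary
    residual inflated by 1/(1 - h_ii), so PRESS >= SSE.
    """
    if sample.n <= model.n_coef + 1:
        raise DomainError(
            f"LOOCV needs n > {model.n_coef + 1}, got n={sample.n}")
    centering_means = (
        (float(sample.x.mean()), float(sample.z.mean())) if model.centering else None)
    design = design_matrix(sample.x, sample.z, model, centering_means)
    coef, _, _, _ = _qr_solve(design, sample.y,
                              {"cell_id": sample.parent_cell_id,
                               "replicate": sample.replicate_index})
    q, _ = np.linalg.qr(design)
    leverages = np.einsum("ij,ij->i", q, q)
    if np.any(leverages >= 1.0 - _LEVERAGE_TOL):
        bad = int(np.argmax(leverages))
        raise DomainError(
            f"observation {bad} has leverage ~1; its leave-one-out "
            "prediction is undefined")
    resid = sample.y - design @ coef
    loo_resid = resid / (1.0 - leverages)
    press = float(loo_resid @ loo_resid)
    y = sample.y
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("degenerate sample: y has zero variance")
    return LoocvResult(r2_cv=1.0 - press / sst, press=press, leverages=leverages)
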