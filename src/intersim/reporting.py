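"""Table writers and the run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Union

import pandas as pd

from .errors import ConfigurationError

_DATA_DICTIONARY = """\
# Output data dictionary

All CSVs are tidy (one row per record or per group) with a fixed header and
full-precision floats; presentation rounding is left to the reader.

Common columns
  cell_id        stable identifier of a grid condition
  shape          interaction shape: synergistic / antagonistic / buffering / none
  noise_level    error-SD multiplier (lambda)
  correlation    generating correlation between the predictors
  beta0..beta3   generating regression weights
  n              sample size drawn from the population
  replicate      replicate index within (cell, n)
  k              number of analyses contributing to a grouped row

Per-replicate records (records.csv)
  b*_simple / b*_inter       fitted coefficients per model
  se_b*_*, p_b*_*            classical standard errors and two-sided t p values
  r2s_*                      in-sample R-squared
  r2p_*                      coefficients re-scored on the full population
  overfit_*                  r2s - r2p
  dr2s, dr2p, doverfit       interaction-minus-simple contrasts of the above
  r2cv_*                     leave-one-out cross-validated R-squared (optional)

Grouped summaries (summary_by_noise.csv / summary_by_n.csv)
  <measure>_q10 / _mdn / _q90   quantiles (linear interpolation)
  <measure>_pct_neg             percent of strictly negative values

Power table (power.csv)
  pct_significant   percent of replicates with p < alpha per
                    (model, coefficient, beta3, n)

Bias table (bias_table.csv)
  b_e0..b_e2        closed-form expected simple-effects coefficients
  bias_*            expected minus generating weight
  *_cancelled       expected coefficient is exactly 0
  *_sign_flip       expected coefficient opposes the generating sign
"""


def file_sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def write_tables(summaries: dict[str, pd.DataFrame],
                 out_dir: Union[str, Path]) -> dict[str, Path]:
    """Write each summary as ``<name>.csv`` with stable column order.

    A data dictionary is emitted alongside.  Re-running with identical inputs
    produces byte-identical files.
    """
    if not summaries:
        raise ConfigurationError("no summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, frame in summaries.items():
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    dictionary = out_dir / "data_dictionary.md"
    dictionary.write_text(_DATA_DICTIONARY)
    paths["data_dictionary"] = dictionary
    return paths


@dataclass
class Manifest:
    """Reproducibility record for one grid run."""

    config: dict[str, Any]
    master_seed: int
    n_conditions: int
    n_records: int
    n_skipped: int
    skipped: list = field(default_factory=list)
    files: dict[str, str] = field(default_factory=dict)
    artifact: str = "intersim"
    version: str = "0.1.0"

    def write(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True,
                                   default=str) + "\n")
        return path

    @classmethod
    def read(cls, path: Union[str, Path]) -> "Manifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
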