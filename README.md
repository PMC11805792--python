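# intersim

Monte-Carlo study of interaction (moderation) effects in linear regression.

`intersim` generates large finite synthetic populations with a known
product-term structure, fits a correctly specified interaction model and a
misspecified simple-effects model to repeated samples, and quantifies:

- **estimation bias** of the misspecified model, including the closed-form
  expected coefficients, cancellation points and sign flips;
- **statistical power** per coefficient, model and interaction shape;
- **overfit and generalizability** through in-sample R², population R²
  (sample coefficients re-scored on the full population), and their
  model contrasts;
- **effect sizes** (incremental f² across the whole design grid) and the
  leave-one-out cross-validated R² proxy for population generalizability.

## Layout

| module | role |
| --- | --- |
| `intersim.grid` | parameter-space enumeration, interaction-shape typology, exact analysis counts |
| `intersim.population` | synthetic populations (bivariate-normal predictors, calibrated noise) and repeated sampling |
| `intersim.ols` | QR-based OLS for both models, classical SEs, t-based p values, centering comparison |
| `intersim.bias` | closed-form expected misspecified coefficients, tipping points, residual-structure diagnostics |
| `intersim.metrics` | f², population R², overfit, model contrasts, normalized RMSE |
| `intersim.loocv` | PRESS-form leave-one-out cross-validated R² |
| `intersim.experiment` | per-cell simulation kernel, grid orchestration, grouped quantile/power tables, f² survey |
| `intersim.config` / `intersim.cli` / `intersim.reporting` | config files (TOML/YAML), CLI, CSV writers, manifest |

## CLI

```sh
# full orchestration at desk scale (populations 1e4, 100 reps, n in {25,100,1000})
intersim run-grid --profile desk --seed 1 --out out/

# single condition, with the per-replicate record stream
intersim run-cell --profile desk --index 0 --seed 1 --out cell.csv

# closed-form expected-estimate table for any grid slice
intersim bias-table --out bias.csv

# population-level interaction effect sizes across the grid
intersim f2-survey --profile desk --population-size 100000 --seed 1 --out f2.csv

# re-aggregate a saved record stream
intersim tables --records cell.csv --by n --out tables/
intersim power --records cell.csv --out power.csv
```

A TOML/YAML config file (`--config`) can override the grid, population size,
replicate count, sample sizes, alpha, seed, centering and LOOCV options; see
`intersim.config`.  Unknown keys are rejected.  All runs are deterministic
given `--seed`: the master seed is split into per-condition and per-replicate
substreams, so any cell is reproducible in isolation.

## Notes on scale

The full-scale design (populations of 1e6, 1000 replicates, six sample sizes,
9216 conditions — about 55M analyses) is far beyond desk scale.  The shipped
`desk` profile and the acceptance script reproduce the aggregate medians and
percentages within Monte-Carlo tolerance in minutes.  One deliberate
deviation: the no-interaction generalizability percentage at n = 1000 uses a
population of 3e5 rather than 1e4, because a 10% sampling fraction couples
the sample to the population it is scored on and visibly depresses that
percentage (see `scripts/acceptance.py`).
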