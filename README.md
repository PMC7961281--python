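# amreml

Pedigree-based animal-model REML for selection-bred populations:
maternal and permanent-environment variance components, BLUP breeding
values, genetic and phenotypic trends, and a breeding-design simulator —
with a command-line interface covering the whole workflow.

The package is aimed at the classic poultry/livestock nucleus-flock
analysis: screen fixed effects by least squares, fit six competing animal
models by REML, pick the best by likelihood-ratio test, report
heritabilities (direct, maternal, total), genetic correlations between
traits, breeding values, and trends across generations.

## What it does

- **Pedigree algebra** — tabular numerator relationship matrix A,
  Meuwissen–Luo inbreeding coefficients, sparse Henderson A⁻¹ with
  inbreeding, all invariant to the input order of pedigree rows.
- **Fixed-effect screening** — sum-to-zero coding, least-squares means,
  Type-III F tests; factors are retained at a configurable α.
- **Six animal models** via REML on sparse mixed-model equations:

  | model | random terms |
  |---|---|
  | 1 | direct additive |
  | 2 | direct + maternal additive (cov = 0) |
  | 3 | direct + maternal additive + covariance |
  | 4 | direct + maternal permanent environment |
  | 5 | direct + maternal additive + maternal PE (cov = 0) |
  | 6 | direct + maternal additive + covariance + maternal PE |

- **Genetic parameters** — h², m², c², r_am, total heritability
  h²_T = h² + 0.5 m² + 1.5 m·r_am·h, with delta-method standard errors;
  LRT-based model selection favouring parsimony.
- **Bivariate REML** — genetic / PE / environmental / phenotypic
  correlations between trait pairs, with likelihood-ratio significance
  tests from constrained refits.
- **BLUP breeding values** for every pedigree member and **trends**
  (regression of generation means on generation).
- **Simulator** — configurable nucleus scheme (default 50 sires × 250
  dams 1:5, 12 progeny/dam, hatches, truncation selection with
  relative-mating avoidance), gene-dropped breeding values whose
  covariance is exactly σ²aA. Fully seed-deterministic.

See [docs/methods.md](docs/methods.md) for the statistical and numerical
details and their verification.

## Quick start (CLI)

Simulate a small three-generation selection experiment, compare models,
and fit:

```sh
amreml simulate --seed 42 --sires 20 --dams-per-sire 4 \
    --progeny-per-dam 6 --generations 3 \
    --selected-males 30 --selected-females 85 \
    --trait SL6 --out-prefix flock
# simulated 1540 animals, 1440 records
#   -> flock_pedigree.csv, flock_phenotypes.csv, flock_truths.csv

amreml select --pedigree flock_pedigree.csv \
    --data flock_phenotypes.csv --trait SL6 --models 1,4 \
    --factors generation,hatch,sex --out select.json
#  model_id  n_params      logL  converged
#         1         2 -4513.491       True
#         4         3 -4512.315       True
#  best model: 1
```

The LRT keeps model 1 (the maternal-PE variance in model 4 is not
significant at this sample size); `select.json` carries the winning fit:
σ²a = 3.51, σ²e = 27.94, h² = 0.112 ± 0.039.

Other subcommands: `lsmeans` (factor screening), `fit` (one model, with
`--bv-out` for the breeding-value CSV), `bivariate` (trait-pair
correlations), `trend` (genetic from a BV file or phenotypic from data),
and `run` for the full pipeline from a YAML config:

```yaml
# run.yaml
pedigree: flock_pedigree.csv
phenotypes: flock_phenotypes.csv
outdir: out
seed: 42
traits:
  - name: SL6
    factors: [generation, hatch, sex]
    models: [1, 2, 4, 5]
pairs: []
```

```sh
amreml run --config run.yaml
```

writes `out/report.json` (full precision), `out/report.md` (readable,
with `NA` for components the chosen model does not carry), and
`out/bv_<trait>.csv` per trait. Reports are deterministic given the data
and seed.

## Quick start (Python)

```python
from amreml import (read_pedigree, FixedEffectSpec, fit_univariate,
                    derive_parameters, select_best_model)
import pandas as pd

ped = read_pedigree("flock_pedigree.csv")
data = pd.read_csv("flock_phenotypes.csv", dtype={"animal": str, "dam": str})
fixed = FixedEffectSpec.from_data(data, ["generation", "hatch", "sex"])

fits = [fit_univariate(ped, data, "SL6", m, fixed=fixed) for m in (1, 4)]
best = select_best_model(fits)
fit = next(f for f in fits if f.model.model_id == best.best_model_id)
p = derive_parameters(fit)
print(f"h2 = {p.h2:.3f} ± {p.h2_se:.3f}")
print(fit.bv.head())          # BLUP breeding values, all pedigree members
```

## Tests

```sh
python -m pytest -q tests/
```

The suite (127 tests, ~4 minutes) checks the sparse REML likelihood and
BLUP against independent dense-matrix oracles, LS means and Type-III F
against statsmodels, pedigree identities (F = diag(A) − 1, A·A⁻¹ = I),
scaling/location invariances, simulator moment checks against theory,
and end-to-end CLI/pipeline determinism, plus property-based tests
(hypothesis) on randomly generated pedigrees.

`scripts/acceptance.py --seed N --out results/acceptance.json` runs a
larger end-to-end calibration: it simulates replicate datasets under a
known architecture and reports the mean model-4 REML heritability, which
should recover the simulated truth (≈ 0.17).

## Layout

```
src/amreml/
  pedigree.py   A, A⁻¹, inbreeding, pedigree IO and validation
  design.py     sum-to-zero coding, LS means, Type-III F
  varcomp.py    univariate + bivariate REML, MME, BLUP, SEs
  params.py     h²/m²/c²/r_am/h²_T, LRT, model selection, correlations
  trends.py     genetic/phenotypic trends, inbreeding summary
  simulate.py   breeding-design simulator and gene dropping
  pipeline.py   end-to-end analysis + JSON/markdown reports
  cli.py        `amreml` command-line interface
docs/methods.md statistical and numerical documentation
tests/          unit, property and acceptance tests (with dense oracles)
```
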