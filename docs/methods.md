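# Methods

This document describes the statistical models, the numerical methods used
to fit them, and the deliberate limitations of each. It is written for a
quantitative geneticist who wants to know exactly what the numbers mean,
and for a developer who needs to know which identities the test suite
holds the code to.

## 1. Pedigree algebra (`amreml.pedigree`)

A pedigree is a list of (animal, sire, dam) triples. Unknown parents are
coded `0` (or `NA`/empty, configurable via `PedigreeDialect`). Animals
that appear only as parents are added as founders automatically unless
strict mode is requested. Duplicated animals, self-parenting, and cycles
are rejected with `PedigreeError`.

**Canonical ordering.** Internally, animals are sorted by (ancestral
depth, canonical id key), where depth is 0 for founders and
1 + max(parent depths) otherwise. This is a topological order (parents
always precede offspring), and because the tie-break is a deterministic
key on the id itself, the internal order — and every matrix derived from
it — is invariant under any permutation of the input rows. The property
suite verifies this with randomly generated and shuffled pedigrees.

**Inbreeding.** Inbreeding coefficients F are computed with the
Meuwissen–Luo algorithm: for each animal, traverse its ancestor list
accumulating within-animal relationship contributions, in O(total ancestor
count) without forming A. `extend_inbreeding` supports incremental
extension of F when new animals are appended to an existing pedigree, and
is tested to agree exactly with a one-shot computation.

**Relationship matrices.** `additive_relationship` builds the numerator
relationship matrix A by the tabular method (dense; guarded by a
`dense_cap` because A is O(n²)). `a_inverse` builds A⁻¹ directly and
sparsely with Henderson's rules including inbreeding: for each animal with
Mendelian-sampling variance ratio

    d_i = 0.5 − 0.25 (F_s + F_d),

with F = −1 substituted for an unknown parent (so a founder has d = 1 and
an animal with one known parent d = 0.75), add kᵢkᵢᵀ/dᵢ to A⁻¹ where kᵢ
has +1 on the animal and −0.5 on each known parent. The identities the
tests enforce: F = diag(A) − 1 to 1e−12, A·A⁻¹ = I to 1e−8, and
log|A| = Σ log dᵢ against a dense slogdet.

## 2. Fixed effects (`amreml.design`)

Fixed factors (e.g. hatch, sex, generation) are coded **sum-to-zero**: a
factor with k levels contributes k−1 columns, the last level carrying −1
in each. With this coding the intercept is the grand mean over a balanced
population of levels, and the least-squares mean of level j is simply
intercept + effect_j (the omitted level's effect is minus the sum of the
others). `ls_means` returns LS means per level plus a **Type-III F test**
per factor, computed by refitting with that factor's columns dropped
(valid here because factors enter additively without interactions).
Factors with p ≤ α (default 0.05) are flagged as retained; the pipeline
carries only retained factors into the animal models. Both the LS means
and the F tests are verified against statsmodels (`anova_lm(typ=3)` and a
prediction-grid LSM construction) in the test suite; statsmodels is a
test-only dependency.

Inestimable levels (no records) yield NaN means rather than an error;
rank deficiency across factors raises `DesignError`.

## 3. Univariate REML (`amreml.varcomp`)

Six nested animal models are supported for a trait y:

| id | random effects | components |
|----|----------------|------------|
| 1 | direct additive | σ²a, σ²e |
| 2 | + maternal additive, cov(a,m)=0 | σ²a, σ²m, σ²e |
| 3 | + cov(a,m) | σ²a, σ_am, σ²m, σ²e |
| 4 | direct + maternal permanent environment | σ²a, σ²c, σ²e |
| 5 | direct + maternal additive + maternal PE, cov=0 | σ²a, σ²m, σ²c, σ²e |
| 6 | model 5 + cov(a,m) | σ²a, σ_am, σ²m, σ²c, σ²e |

with y = Xβ + Z_a a + Z_m m + Z_c c + e, (a, m) ~ N(0, G₀ ⊗ A),
c ~ N(0, σ²c I over dams), e ~ N(0, σ²e I). Models with maternal terms
require a `dam` column in the data; records with unknown dams are dropped
for those models (and the fit reports how many).

**Likelihood.** The REML log-likelihood is evaluated through the sparse
mixed-model equations. With C the MME coefficient matrix,

    −2 logL = (n − p) log 2π + (n − p_used) terms folded as:
    −2 logL = (n − p) log 2π + n_e log σ²e + log|G| + log|C| + y'Py,
    y'Py   = y'R⁻¹y − sol'·rhs,

where log|G| uses log|A| = Σ log dᵢ per additive effect (and the 2×2 G₀
determinant for correlated a, m), and log|C| comes from a sparse LU
factorisation (`splu` with `permc_spec="MMD_AT_PLUS_A"`, symmetric mode).
The test suite holds this to ≤1e−8 against an independent dense oracle
that forms V = ZGZ' + R explicitly and computes
(n−p) log 2π + log|V| + log|X'V⁻¹X| + y'Py — for all six models at
multiple parameter values.

**Optimisation.** Parameters are transformed to an unconstrained scale —
log for variances, atanh for the (a, m) correlation — and minimised with
Nelder–Mead. Convergence: variance of −2logL over the simplex < 1e−8;
the search restarts from the incumbent until a restart improves logL by
< 1e−6. This resolves logL to roughly 1e−4, which bounds what
model-comparison tests may assume (the nesting-monotonicity test allows a
1e−3 slack for this reason). Warm starts from a previous `FitResult` are
supported and used by the pipeline. Degenerate designs (e.g. maternal
effects with every dam unknown, or a PE effect with one progeny per dam
everywhere) raise `NonIdentifiableError`/`ModelError` up front.

**BLUP.** Solving the MME at the REML estimates gives GLS fixed-effect
estimates and BLUP of all random effects for every pedigree member,
records or not. Tested to ≤1e−8 against the dense identity
û = Cov(u, y) V⁻¹ (y − X β̂_GLS).

**Standard errors.** The observed information is approximated by
finite-difference Hessian of −2logL/2 at the optimum on the original
scale, with step sizes h = max(0.05|θ|, 1e−3·scale) — large steps are
deliberate, because the optimum is known only to optimizer resolution and
tiny steps amplify that noise. Ratio SEs (h², etc.) use the delta method;
the delta-method machinery is verified against analytic gradients for h²
and σ²p in model 1.

## 4. Bivariate REML and correlations

`fit_bivariate` fits two traits jointly under their (possibly different)
univariate model structures, estimating a 2×2 (co)variance block per
shared random effect plus the residual block. Blocks are parameterised as
(log var_x, log var_y, atanh r), guaranteeing positive-definite blocks.
The implementation assumes **equal design**: both traits measured on the
same records with the same fixed-effect incidence. This admits a
factorisation of the MME through precomputed single-trait cross-product
blocks combined with R₀⁻¹ entries, which keeps the joint fit tractable;
the likelihood is nevertheless verified against a fully general stacked
dense oracle. Warm-starting from the two univariate fits is strongly
recommended (the pipeline does it automatically) and typically cuts the
fit time by an order of magnitude.

Named correlations can be **pinned** via `constraints` (e.g.
`{"r_a": 0.0}`), enabling likelihood-ratio tests of individual
correlations: `correlation_significance` reports each correlation with a
1-df LRT p-value where a constrained refit is supplied, and a t-type test
for the phenotypic correlation. Without a refit the p-value is NaN, never
silently 0 or 1.

## 5. Genetic parameters and model selection (`amreml.params`)

From a fit, `derive_parameters` computes

    σ²p = σ²a + σ²m + σ_am + σ²c + σ²e   (absent terms omitted, not zero)
    h² = σ²a/σ²p, m² = σ²m/σ²p, c² = σ²c/σ²p, r_am = σ_am/(σ_a σ_m)
    h²_T = h² + 0.5 m² + 1.5 m r_am h     (total heritability,
                                           m = √m², h = √h²)

Note σ_am enters σ²p once (not twice): the phenotypic variance of an
individual sums its direct variance, its dam's maternal contribution and
their covariance as expressed in a single record. Components a model does
not carry are reported as `None`/NA — never conflated with an estimate
of zero.

`select_best_model` walks the nesting lattice of the fitted models
(1⊂2⊂3, 1⊂4⊂5⊂6, 2⊂5, 2⊂3, 3⊂6, 5⊂6, …): a larger model is preferred
only if the likelihood-ratio test against the best current model rejects
at α (χ² with df = difference in parameter count, statistic floored at
0); among models the data cannot distinguish, the most parsimonious wins.
Unconverged fits are excluded; if none converged the comparison raises.

## 6. Trends and inbreeding (`amreml.trends`)

`genetic_trend` regresses per-generation mean BLUP breeding value on
generation number (ordinary least squares on the generation means, with
slope SE, t-test p-value and R²); `phenotypic_trend` does the same with
phenotype means. Fewer than 3 generations is an error, not a silent NaN.
`inbreeding_summary` reports mean F overall, mean F among inbred animals
(F > 0), and the inbred count.

These are descriptive trends: OLS on generation means ignores drift
covariance between generations, so the p-values are anti-conservative for
strongly drifting populations. They are intended as monitoring summaries,
not formal tests of selection response.

## 7. Breeding-design simulator (`amreml.simulate`)

`simulate_dataset` generates a pedigree, true breeding values, and
phenotypes for a configurable nucleus breeding scheme, default
50 sires × 250 dams mated 1:5, 12 progeny per dam, across hatches and
generations, with truncation selection (default 200 males + 450 females
on the selection trait; ties broken deterministically by id) and
**mate avoidance**: a dam is not assigned to a sire with whom she shares
a parent or grandparent. Assignment is greedy with a swap-repair pass —
before the avoidance rule is ever relaxed, the assigner tries to swap
with a compatible dam already assigned to an earlier sire; relaxation
logs a warning.

True breeding values are **gene-dropped**: a founder draws
N(0, σ²a); a non-founder draws 0.5(a_s + a_d) plus a Mendelian-sampling
deviation with the exact variance dᵢσ²a, dᵢ = 0.5 − 0.25(F_s + F_d), so
the simulated BVs have covariance σ²aA exactly, including inbred
diagonals — verified empirically over thousands of replicate drops.
Maternal PE effects are drawn per dam; phenotypes add hatch, sex and
generation fixed effects and N(0, σ²e) residuals. Multiple traits may be
simulated with specified genetic and environmental correlations.
`default_architectures()` ships a set of growth/production trait
architectures usable out of the box. All randomness flows from a single
integer seed; identical seeds give bit-identical outputs.

The simulator is a design tool, not a genome simulator: it has no loci,
no linkage, no dominance/epistasis, and the infinitesimal model is exact
by construction.

## 8. Pipeline and reporting (`amreml.pipeline`, CLI)

`run_pipeline` ties the stages together per trait: LS-means screening →
retained factors → fit the candidate models → LRT selection →
parameters with SEs → breeding-value CSV → genetic and phenotypic
trends; then bivariate fits with constrained refits for each requested
trait pair, and a pedigree inbreeding summary. The report is written as
`report.json` (full precision) and `report.md` (rounded; missing values
rendered `NA`). Parameter tables always use the canonical row order
σ²a, σ²m, σ_am, σ²c, σ²e, σ²p, h², m², r_am, c², h²_T, logL. The report
records the package version, the seed, and a hash of the configuration
(excluding the output directory, so the same analysis hashes identically
wherever it is written). A stage failure dumps a `partial_report.json`
with everything completed so far before raising.

## 9. Problem-size guidance

The MME is sparse; cost is dominated by the sparse LU of C at each
likelihood evaluation. Pedigrees up to a few tens of thousands of animals
with a handful of fixed-effect levels fit comfortably in seconds to
minutes per univariate model on one core (a 3,000-record, 3,300-animal
model-4 fit takes ~4 s). Dense A via `additive_relationship` is capped
(default 5,000 animals) and is only needed for diagnostics — REML and
BLUP never form A. Bivariate fits cost roughly an order of magnitude more
than univariate; always warm-start them. `compute_se=False` skips the
Hessian and is the right choice inside simulation loops.
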