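# Methods

This document records the statistical models, algorithms and design
decisions behind `cortexeval`, in enough detail to re-derive every number
the package produces.

## Units and conventions

- Thickness is in millimetres; visit time is in **months**; slopes are
  mm/month. Ages are in years.
- The 62 regions are 31 labeled gyral regions per hemisphere, columns
  `lh_<abbr>` / `rh_<abbr>` in protocol order (`cACC` … `INS`).
- All randomness flows from one master seed through
  `cortexeval._utils.derive_seed`, which hashes `(seed, *tokens)` with
  BLAKE2b and reduces modulo 2³¹−1. Per-region, per-chain, per-permutation
  seeds are derived, never incremented, so results are independent of
  execution order and fully reproducible.

## Cohort generator

Cross-sectional: `Y = α₀ + s·age + g·gender + u + ε`, with `u ~ N(0, τ²)`
per subject and `ε ~ N(0, σ²)` per measurement. Longitudinal: per-subject
intercepts `a_i ~ N(α₀, τ²)` and slopes `b_i ~ N(β₀ + δ_dx, ρ²)` (one slope
offset `δ` per diagnostic group), an additive time-constant site intercept
`N(0, site_sd²)`, and i.i.d. residual noise; dropout (when enabled)
truncates each subject's schedule to a prefix. Scan–rescan: the shared
subject truth plus two independent residual draws, tagged by an
`acquisition` column. The pipeline emulator produces `B = A + bias +
N(0, noise_sd²)` cell-wise.

Defaults mimic a three-group longitudinal study (197/324/142 subjects,
visits every 6 months to 36) and a lifespan age range; both are package
choices, configurable via `CohortConfig`. Generated thickness is clipped
at a small positive floor (count recorded in `attrs["n_clipped"]`; zero at
default noise levels). The generator is a calibration instrument: it makes
no claim to reproduce real acquisition physics, scanner differences, or
non-linear aging.

## Variance-ratio model and sampler

Per region:

```
Y_ij ~ N(a_i + b_i t_ij, σ²)
a_i ~ N(α₀, τ²),  b_i ~ N(β₀, ρ²)
α₀, β₀ ~ N(0, 10²),  σ, τ, ρ ~ half-Cauchy(0, 5)
```

The headline quantity is `r = τ/σ` (posterior median, central 95%
interval). `r` is invariant to affine changes of the response, which the
acceptance suite checks directly.

Blocked Gibbs sampler:

1. **Per-subject (a_i, b_i)**: bivariate conjugate Normal updates,
   vectorized across subjects via sufficient statistics and a closed-form
   2×2 Cholesky.
2. **α₀, β₀**: conjugate Normal given the subject effects.
3. **Scales σ, τ, ρ**: the half-Cauchy(0, A) prior on a scale `s` is
   represented by parameter expansion,
   `s² | g ~ Inv-Gamma(1/2, 1/g)`, `g ~ Inv-Gamma(1/2, 1/A²)`,
   giving conjugate inverse-gamma updates. An independent stepping-out
   slice sampler on `log s` is available (`scale_sampler="slice"`); the
   test suite asserts the two routes agree.

Four chains of 2000 iterations with 1000 warm-up are the defaults; R-hat
and effective sample size are computed with ArviZ. R-hat above 1.1 sets a
`converged_` warning flag rather than raising: at short chain lengths the
slope-scale `ρ` can mix slowly (the usual funnel as `ρ → 0`), but `r`
involves only `τ` and `σ`, which mix well; the flag makes the caveat
visible without blocking the pipeline comparison. Data in which every
subject has a single visit make `τ` and `σ` non-identifiable and raise
`NonIdentifiableError`.

### Oracles

- **Grid integration**: with slopes off, `(a_i, α₀)` marginalize
  analytically — the stacked data are `N(0, blockdiag(σ²I + τ²J) +
  s₀²·11ᵀ)` — leaving a 2-D `(τ, σ)` posterior evaluated by brute-force
  quadrature (`reference.grid_posterior_medians`). The grid upper limit is
  several pooled standard deviations wide because the half-Cauchy tail is
  heavy at tiny n.
- **Conjugate closed form**: with the scales fixed, the `α₀` posterior is
  an exact Normal (`reference.intercept_posterior_closed_form`), matched by
  the sampler to three decimals in the tests.

## Cross-sectional evaluation

- **Age prediction**: a random forest regresses age on ICV, gender and the
  62 thickness values; repeated random 80/20 train/test splits (default
  500; stratified by site when feasible) give an RMSE distribution. The
  repeated splits are Monte-Carlo cross-validation resplits — "permutation"
  in the API names the resplit index, not a label permutation. Two
  closed-form checks: pure-noise features must approach the RMSE of
  predicting the mean of `Uniform(a, b)` ages, `(b−a)/√12`; a noiseless
  linear age encoding must be learned to within small error.
- **Lifespan models**: per region, OLS of thickness on gender and age. The
  radar table predicts thickness at ages 25/50/75 for both genders and
  divides by the single largest predicted value across all
  (pipeline, region, age, gender) cells; exactly one cell is the
  reference. Pipelines are compared by a paired t-test over matched cells.
- **ICC**: "average random rater" reliability is ICC(2,k) — two-way
  random effects, average measures — computed from the ANOVA mean squares
  `(MSR − MSE) / (MSR + (MSC − MSE)/n)`. It is exact (1.0) for identical
  acquisitions, affine-invariant, and cross-checked in the tests against a
  hand-computed 5×2 table and an independent library implementation.

## Longitudinal contrasts

Per region, the baseline-change response `ΔY = Y(t) − Y(0)` is modeled as

```
ΔY ~ Y_bl + AGE_bl + ICV_bl + APOE_bl + GENDER + DIAGNOSIS_bl
     + VISIT:DIAGNOSIS_bl + (1 | subject) + (1 | site)
```

fitted by REML (statsmodels MixedLM; subjects as variance components
nested within site groups, matching the crossed intercepts for this
design). The `VISIT:DIAGNOSIS` interaction gives one change-trajectory
slope per group; pairwise differences (LMCI−CN, AD−LMCI, AD−CN) are tested
with the studentized-range (Tukey) distribution at k = 3 and the model's
residual degrees of freedom (containment: observations minus fixed
effects). `(AD−CN) = (AD−LMCI) + (LMCI−CN)` holds exactly by construction
of the contrast vectors.

**Site variance and the boundary flag.** The generator adds its site
intercept to `Y` itself, so the site term cancels exactly in `ΔY` and the
fitted site variance collapses to zero. The `(1 | site)` term is kept —
the model structure, not the generator, is the contract, and real pipelines
can produce site-dependent change — but a collapse of either random-effect
variance to (numerically) zero, or an optimizer non-convergence, is
reported per region as `boundary_fit_flag` instead of being raised.

Benjamini–Hochberg FDR is applied across the 62 regions **within each
contrast** by default (the three contrasts answer distinct questions;
`fdr_family="global"` pools all 186 tests). `log10_p_fdr` is floored at
1e-300 before taking the logarithm.

## Problem sizes and budgets

Replicate counts, chain lengths and cohort sizes used in the tests and in
`scripts/acceptance.py` are the package's own reduced one-CPU settings;
the estimators default to the full-size settings (500 resplits, 4×2000
MCMC). All acceptance quantities are recomputed at runtime from the
generators above — none are stored constants.
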