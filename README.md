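# cortexeval

A statistical evaluation framework for regional cortical-thickness pipelines.

Image-processing pipelines that measure cortical thickness differ in bias and
noise, and the scientifically relevant question is rarely "which numbers are
larger" but "which measurements better separate signal from noise".
`cortexeval` provides a self-contained harness for answering that question on
synthetic cohorts with known ground truth:

- **Cohort synthesis** — cross-sectional, longitudinal (three diagnostic
  groups with distinct atrophy slopes, multi-site, optional dropout), and
  scan–rescan cohorts over 62 cortical regions (31 per hemisphere), plus an
  emulator that derives a paired "pipeline B" variant of any table by adding
  a constant bias and independent measurement noise.
- **Variance-ratio model** — a Bayesian hierarchical linear mixed-effects
  model fitted per region by a built-in Gibbs sampler; its headline quantity
  is the ratio of between-subject to residual variability, `r = τ/σ`, with
  posterior median and 95% credible interval. Larger `r` means the
  measurement better distinguishes individuals from noise.
- **Cross-sectional evaluation** — a Monte-Carlo cross-validated
  random-forest age-prediction harness (RMSE in years), per-region lifespan
  linear models with a relative-thickness radar table and a paired t-test,
  and scan–rescan reliability via ICC(2,k).
- **Longitudinal contrasts** — per-region baseline-change mixed models with
  subject and site random intercepts, Tukey-adjusted pairwise diagnostic
  contrasts (LMCI−CN, AD−LMCI, AD−CN), and Benjamini–Hochberg FDR across
  regions.
- **Reporting CLI** — a `cortexeval` executable with one subcommand per
  stage, a manifest-driven `run-all`, and a schema `validate` command. All
  artifacts are plain CSV/JSON with content checksums for reproducibility.

## The model

Per region, for subject *i* at visit time *t* (months):

```
Y_it ~ Normal(a_i + b_i t, σ²)
a_i  ~ Normal(α₀, τ²)          b_i ~ Normal(β₀, ρ²)
α₀, β₀ ~ Normal(0, 10²)        σ, τ, ρ ~ half-Cauchy(0, 5)
```

The variance ratio `r = τ/σ` is summarized by its posterior median and
central 95% credible interval. See `docs/methods.md` for the sampler,
diagnostics, oracles, and design decisions.

## Worked example

```python
import cortexeval as ce

cfg = ce.adni_like_config(seed=7, group_sizes={"CN": 40, "LMCI": 40, "AD": 40},
                          n_sites=4)
subjects, visits = ce.generate_longitudinal(cfg)   # 840 rows x 70 columns

# variance ratio for one region
series = visits.rename(columns={"lh_ENT": "y"})[
    ["subject_id", "visit_time_months", "y"]]
m = ce.BayesianLME(n_chains=2, n_iterations=800, n_warmup=300, seed=1).fit(series)
print(m.r_median_, m.r_ci_95_)     # 3.25, (2.81, 3.78)

# scan-rescan reliability
rescan = ce.generate_scan_rescan(cfg, 60, seed=3)
iccs = [r.icc_value for r in ce.compute_icc(rescan)]   # median 0.950

# longitudinal diagnostic contrasts with FDR
results = ce.run_longitudinal_evaluation(visits)
print((results["p_fdr"] < 0.05).sum(), "of", len(results))   # 68 of 186
```

With this seed the entorhinal AD−CN trajectory difference is estimated at
−0.00262 mm/month (FDR-adjusted p ≈ 2.1e-3); the generative offset is
−0.0025 mm/month.

From the command line:

```bash
cortexeval simulate --mode long --seed 7 --out cohort.csv
cortexeval variance-ratio --in cohort.csv --out vr.csv
cortexeval run-all --config examples/manifest.yaml --seed 0 --out results/
cortexeval validate --in cohort.csv
```

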