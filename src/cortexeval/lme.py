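"""Bayesian hierarchical linear mixed-effects model and the variance ratio.

Per region k, with Y_ij the thickness of subject i at visit time t_ij
(months):

    Y_ij   ~ Normal(a_i + b_i * t_ij, sigma^2)
    a_i    ~ Normal(alpha0, tau^2)        b_i ~ Normal(beta0, rho^2)
    alpha0, beta0 ~ Normal(0, mean_prior_sd^2)
    sigma, tau, rho ~ half-Cauchy(0, cauchy_scale)

The reliability summary is the variance ratio r = tau / sigma: the spread
of true subject-level values relative to measurement noise. Posteriors are
sampled by a blocked Gibbs sampler. The half-Cauchy priors are handled by
the inverse-gamma parameter-expansion identity

    s^2 | g ~ InvGamma(1/2, 1/g),  g ~ InvGamma(1/2, 1/A^2)
        ==>  s ~ half-Cauchy(0, A),

which keeps every update conjugate; a stepping-out slice sampler on log s
is available as an independent fallback (``scale_sampler="slice"``) and the
two must agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

try:  # BaseEstimator gives get_params/set_params and sklearn composability
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    BaseEstimator = object

from ._utils import derive_seed
from .config import McmcConfig, PriorConfig
from .errors import ConfigurationError, NonIdentifiableError, SchemaError
from .regions import DKT_REGIONS, REGION_CODES

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.1


def _sample_inv_gamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    """One draw from InvGamma(shape, scale) (density ∝ x^{-shape-1} e^{-scale/x})."""
    return scale / rng.standard_gamma(shape)


def _slice_update_log_scale(s0: float, m: float, ss: float, cauchy_scale: float,
                            rng: np.random.Generator, w: float = 1.0,
                            max_steps: int = 100) -> float:
    """Slice-sample a variance scale s from p(s) ∝ s^-m exp(-ss/(2 s^2)) HC(s; A).

    Works on u = log s (Jacobian included); stepping-out then shrinkage.
    """
    a2 = cauchy_scale**2

    def logf(u: float) -> float:
        return (-(m - 1.0) * u - 0.5 * ss * np.exp(-2.0 * u)
                - np.log1p(np.exp(2.0 * u) / a2))

    u0 = np.log(max(s0, 1e-12))
    logy = logf(u0) + np.log(rng.random())
    left = u0 - w * rng.random()
    right = left + w
    for _ in range(max_steps):
        if logf(left) < logy:
            break
        left -= w
    for _ in range(max_steps):
        if logf(right) < logy:
            break
        right += w
    for _ in range(max_steps):
        u = rng.uniform(left, right)
        if logf(u) >= logy:
            return float(np.exp(u))
        if u < u0:
            left = u
        else:
            right = u
    return float(np.exp(u0))  # pragma: no cover - shrinkage always terminates


class BayesianLME(BaseEstimator):
    """Gibbs-sampled hierarchical LME for one region's longitudinal data.

    Parameters
    ----------
    mean_prior_sd : float
        Standard deviation of the Normal(0, .) prior on the population
        intercept and slope (default 10, interpreted as an sd).
    cauchy_scale : float
        Scale of the half-Cauchy prior on sigma, tau, rho (default 5).
    n_chains, n_iterations, n_warmup, seed : int
        MCMC schedule; post-warmup draws from all chains are pooled for
        summaries.
    include_slopes : bool
        When False the per-subject slopes are fixed at zero (intercept-only
        hierarchical model); used for reduced designs and oracle checks.
    scale_sampler : {"px", "slice"}
        Update for the half-Cauchy scales: inverse-gamma parameter expansion
        (conjugate) or slice sampling (independent fallback).
    fixed_scales : dict or None
        Optional {"sigma": v, "tau": v, "rho": v} entries held constant
        instead of sampled; diagnostic/validation use only.

    Attributes (after fit)
    ----------------------
    draws_ : dict of (n_chains, n_kept) arrays for alpha0, beta0, sigma,
        tau, rho and r (= tau/sigma elementwise).
    r_median_, r_ci_95_ : posterior median and central 95% credible interval
        of the variance ratio.
    rhat_, ess_ : per-parameter convergence diagnostics.
    converged_ : False when any R-hat exceeds 1.1 (warning flag, not error).
    """

    def __init__(self, mean_prior_sd: float = 10.0, cauchy_scale: float = 5.0,
                 n_chains: int = 4, n_iterations: int = 2000,
                 n_warmup: int = 1000, seed: int = 0,
                 include_slopes: bool = True, scale_sampler: str = "px",
                 fixed_scales: dict | None = None):
        self.mean_prior_sd = mean_prior_sd
        self.cauchy_scale = cauchy_scale
        self.n_chains = n_chains
        self.n_iterations = n_iterations
        self.n_warmup = n_warmup
        self.seed = seed
        self.include_slopes = include_slopes
        self.scale_sampler = scale_sampler
        self.fixed_scales = fixed_scales

    # ------------------------------------------------------------------ fit
    def fit(self, data: pd.DataFrame, y=None) -> "BayesianLME":
        """Sample the posterior from a long table.

        ``data`` needs columns ``subject_id``, ``visit_time_months`` and
        ``y`` (one region's thickness in mm).
        """
        PriorConfig(self.mean_prior_sd, self.cauchy_scale)  # validate
        McmcConfig(self.n_chains, self.n_iterations, self.n_warmup, self.seed)
        if self.scale_sampler not in ("px", "slice"):
            raise ConfigurationError(f"unknown scale_sampler {self.scale_sampler!r}")

        for col in ("subject_id", "visit_time_months", "y"):
            if col not in data.columns:
                raise SchemaError(f"missing column {col}")
        subj, t, yv = (data["subject_id"].to_numpy(),
                       data["visit_time_months"].to_numpy(dtype=float),
                       data["y"].to_numpy(dtype=float))
        codes, idx = np.unique(subj, return_inverse=True)
        n_subj = len(codes)
        if n_subj < 2:
            raise NonIdentifiableError("need at least 2 subjects")
        counts = np.bincount(idx)
        if counts.max() < 2:
            raise NonIdentifiableError(
                "every subject has a single visit; residual and slope "
                "variability are confounded")

        # per-subject sufficient statistics
        stats = {
            "n": counts.astype(float),
            "St": np.bincount(idx, weights=t),
            "Stt": np.bincount(idx, weights=t * t),
            "Sy": np.bincount(idx, weights=yv),
            "Sty": np.bincount(idx, weights=t * yv),
        }
        n_kept = self.n_iterations - self.n_warmup
        names = ("alpha0", "beta0", "sigma", "tau", "rho")
        draws = {p: np.empty((self.n_chains, n_kept)) for p in names}
        for c in range(self.n_chains):
            rng = np.random.default_rng(derive_seed(self.seed, "chain", c))
            chain = self._run_chain(idx, t, yv, stats, rng)
            for p in names:
                draws[p][c] = chain[p]
        draws["r"] = draws["tau"] / draws["sigma"]

        self.n_subjects_ = n_subj
        self.n_observations_ = len(yv)
        self.draws_ = draws
        self.r_median_, self.r_ci_95_ = _median_and_ci(draws["r"])
        self.rhat_, self.ess_ = _diagnostics(draws)
        self.converged_ = all(v <= RHAT_THRESHOLD for v in self.rhat_.values()
                              if np.isfinite(v))
        if not self.converged_:
            logger.warning("R-hat above %.2f for some parameters: %s",
                           RHAT_THRESHOLD, self.rhat_)
        return self

    # ----------------------------------------------------------- one chain
    def _run_chain(self, idx, t, y, stats, rng) -> dict:
        fixed = dict(self.fixed_scales or {})
        n_subj = len(stats["n"])
        n_obs = len(y)
        s0_prec = 1.0 / self.mean_prior_sd**2
        A = self.cauchy_scale
        slopes = self.include_slopes

        # initial values from per-subject summaries
        subj_mean = stats["Sy"] / stats["n"]
        a = subj_mean.copy()
        b = np.zeros(n_subj)
        alpha0 = float(np.mean(a))
        beta0 = 0.0
        sigma = float(fixed.get("sigma", max(np.std(y - a[idx]), 0.05)))
        tau = float(fixed.get("tau", max(np.std(subj_mean), 0.05)))
        rho = float(fixed.get("rho", 0.01))
        g_sig = g_tau = g_rho = 1.0

        n_kept = self.n_iterations - self.n_warmup
        out = {p: np.empty(n_kept) for p in
               ("alpha0", "beta0", "sigma", "tau", "rho")}

        for it in range(self.n_iterations):
            sig2, tau2, rho2 = sigma**2, tau**2, rho**2

            # --- subject random effects (joint bivariate conjugate update)
            if slopes:
                p11 = stats["n"] / sig2 + 1.0 / tau2
                p12 = stats["St"] / sig2
                p22 = stats["Stt"] / sig2 + 1.0 / rho2
                h1 = stats["Sy"] / sig2 + alpha0 / tau2
                h2 = stats["Sty"] / sig2 + beta0 / rho2
                det = p11 * p22 - p12 * p12
                c11, c12, c22 = p22 / det, -p12 / det, p11 / det
                m1 = c11 * h1 + c12 * h2
                m2 = c12 * h1 + c22 * h2
                l11 = np.sqrt(c11)
                l21 = c12 / l11
                l22 = np.sqrt(np.maximum(c22 - l21 * l21, 1e-300))
                z1 = rng.standard_normal(n_subj)
                z2 = rng.standard_normal(n_subj)
                a = m1 + l11 * z1
                b = m2 + l21 * z1 + l22 * z2
            else:
                prec = stats["n"] / sig2 + 1.0 / tau2
                mean = (stats["Sy"] / sig2 + alpha0 / tau2) / prec
                a = mean + rng.standard_normal(n_subj) / np.sqrt(prec)

            # --- population means
            prec = n_subj / tau2 + s0_prec
            alpha0 = (np.sum(a) / tau2) / prec + rng.standard_normal() / np.sqrt(prec)
            if slopes:
                prec = n_subj / rho2 + s0_prec
                beta0 = (np.sum(b) / rho2) / prec + rng.standard_normal() / np.sqrt(prec)

            # --- variance scales
            resid = y - a[idx] - (b[idx] * t if slopes else 0.0)
            ssr = float(resid @ resid)
            ss_a = float(np.sum((a - alpha0) ** 2))
            if "sigma" not in fixed:
                sigma, g_sig = self._scale_update(sigma, g_sig, n_obs, ssr, A, rng)
            if "tau" not in fixed:
                tau, g_tau = self._scale_update(tau, g_tau, n_subj, ss_a, A, rng)
            if slopes and "rho" not in fixed:
                ss_b = float(np.sum((b - beta0) ** 2))
                rho, g_rho = self._scale_update(rho, g_rho, n_subj, ss_b, A, rng)

            if it >= self.n_warmup:
                j = it - self.n_warmup
                out["alpha0"][j] = alpha0
                out["beta0"][j] = beta0
                out["sigma"][j] = sigma
                out["tau"][j] = tau
                out["rho"][j] = rho
        return out

    def _scale_update(self, s, g, m, ss, A, rng):
        """One update of a half-Cauchy variance scale given m terms with sum
        of squares ss; returns (new scale, new expansion auxiliary)."""
        if self.scale_sampler == "px":
            g = _sample_inv_gamma(1.0, 1.0 / A**2 + 1.0 / s**2, rng)
            s2 = _sample_inv_gamma((m + 1.0) / 2.0, 1.0 / g + ss / 2.0, rng)
            return float(np.sqrt(s2)), g
        return _slice_update_log_scale(s, float(m), ss, A, rng), g


# ----------------------------------------------------------------- summaries

def _median_and_ci(draws_2d: np.ndarray) -> tuple[float, tuple[float, float]]:
    pooled = np.ravel(draws_2d)
    lo, med, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
    return float(med), (float(lo), float(hi))


def _diagnostics(draws: dict) -> tuple[dict, dict]:
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rhat_d = {k: float(rhat[k].values) for k in draws}
    ess_d = {k: float(ess[k].values) for k in draws}
    return rhat_d, ess_d


@dataclass
class RegionPosterior:
    """Posterior summary of the hierarchical LME for one region."""

    region: str
    draws: dict = field(repr=False)   # name -> (n_chains, n_kept) array
    r_median: float = 0.0
    r_ci_95: tuple[float, float] = (0.0, 0.0)
    rhat: dict = field(default_factory=dict)
    ess: dict = field(default_factory=dict)
    converged: bool = True

    def pooled(self, name: str) -> np.ndarray:
        return np.ravel(self.draws[name])

    def median(self, name: str) -> float:
        return float(np.median(self.pooled(name)))


def variance_ratio(posterior: RegionPosterior | BayesianLME
                   ) -> tuple[float, tuple[float, float]]:
    """Posterior median and central 95% credible interval of r = tau/sigma.

    Recomputed elementwise from the tau and sigma draws; requires at least
    100 retained draws.
    """
    draws = posterior.draws if isinstance(posterior, RegionPosterior) else posterior.draws_
    tau = np.ravel(draws["tau"])
    sigma = np.ravel(draws["sigma"])
    if tau.size < 100:
        raise ConfigurationError("need >= 100 retained draws")
    if np.any(sigma <= 0):
        raise RuntimeError("internal consistency error: non-positive sigma draw")
    r = tau / sigma
    lo, med, hi = np.percentile(r, [2.5, 50.0, 97.5])
    return float(med), (float(lo), float(hi))


def fit_region_lme(visits: pd.DataFrame, priors: PriorConfig | None = None,
                   mcmc: McmcConfig | None = None, region: str = "y",
                   **kwargs) -> RegionPosterior:
    """Fit the hierarchical LME to one region's long table (columns
    subject_id, visit_time_months, y) and summarize the posterior."""
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    model = BayesianLME(
        mean_prior_sd=priors.mean_prior_sd, cauchy_scale=priors.cauchy_scale,
        n_chains=mcmc.n_chains, n_iterations=mcmc.n_iterations,
        n_warmup=mcmc.n_warmup, seed=mcmc.seed, **kwargs,
    ).fit(visits)
    return RegionPosterior(
        region=region, draws=model.draws_, r_median=model.r_median_,
        r_ci_95=model.r_ci_95_, rhat=model.rhat_, ess=model.ess_,
        converged=model.converged_,
    )


def fit_all_regions(table: pd.DataFrame, priors: PriorConfig | None = None,
                    mcmc: McmcConfig | None = None,
                    master_seed: int | None = None,
                    **kwargs) -> list[RegionPosterior]:
    """Fit every DKT region of a longitudinal cohort table.

    Seeds are derived per region from the master seed, so results are
    independent of fitting order. Returns 62 RegionPosterior in region-set
    order.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    seed = mcmc.seed if master_seed is None else master_seed
    results = []
    for code in REGION_CODES:
        if code not in table.columns:
            raise SchemaError(f"missing region column {code}")
    for code in REGION_CODES:
        sub = pd.DataFrame({
            "subject_id": table["subject_id"],
            "visit_time_months": table["visit_time_months"],
            "y": table[code],
        })
        region_mcmc = McmcConfig(mcmc.n_chains, mcmc.n_iterations,
                                 mcmc.n_warmup, derive_seed(seed, code))
        results.append(fit_region_lme(sub, priors, region_mcmc,
                                      region=code, **kwargs))
        logger.info("fitted %s: r_median=%.3f", code, results[-1].r_median)
    return results


_HEMI = {r.code: r.hemisphere for r in DKT_REGIONS}


def posterior_summary_frame(results: list[RegionPosterior]) -> pd.DataFrame:
    """Per-region posterior summary table (one row per region)."""
    rows = []
    for res in results:
        rows.append({
            "region": res.region,
            "hemisphere": _HEMI.get(res.region, ""),
            "alpha0": res.median("alpha0"),
            "beta0": res.median("beta0"),
            "tau": res.median("tau"),
            "rho": res.median("rho"),
            "sigma": res.median("sigma"),
            "r_median": res.r_median,
            "r_lo": res.r_ci_95[0],
            "r_hi": res.r_ci_95[1],
            "rhat_max": max(res.rhat.values()) if res.rhat else np.nan,
            "ess_min": min(res.ess.values()) if res.ess else np.nan,
            "converged": res.converged,
        })
    return pd.DataFrame(rows)


def summarize_pipelines(results_per_pipeline: dict[str, list[RegionPosterior]]
                        ) -> pd.DataFrame:
    """Per-pipeline, per-region posterior medians of sigma, tau and r.

    One row per (pipeline, region); the across-region distribution of each
    quantity per pipeline is summarized by :func:`across_region_quartiles`.
    """
    if not results_per_pipeline:
        raise ConfigurationError("need at least one pipeline")
    region_sets = {label: tuple(r.region for r in res)
                   for label, res in results_per_pipeline.items()}
    first = next(iter(region_sets.values()))
    if any(rs != first for rs in region_sets.values()):
        raise ConfigurationError("pipelines cover different region sets")
    rows = []
    for label, results in results_per_pipeline.items():
        for res in results:
            rows.append({
                "pipeline": label,
                "region": res.region,
                "hemisphere": _HEMI.get(res.region, ""),
                "sigma_median": res.median("sigma"),
                "tau_median": res.median("tau"),
                "r_median": res.r_median,
                "r_lo": res.r_ci_95[0],
                "r_hi": res.r_ci_95[1],
            })
    return pd.DataFrame(rows)


def across_region_quartiles(summary: pd.DataFrame) -> pd.DataFrame:
    """Quartiles of the per-region medians across the 62 regions, per
    pipeline and parameter; long format (pipeline, parameter, q25, q50, q75)."""
    rows = []
    for label, grp in summary.groupby("pipeline", sort=False):
        for param, col in (("sigma", "sigma_median"), ("tau", "tau_median"),
                           ("r", "r_median")):
            q25, q50, q75 = np.percentile(grp[col].to_numpy(), [25, 50, 75])
            rows.append({"pipeline": label, "parameter": param,
                         "q25": q25, "q50": q50, "q75": q75,
                         "iqr": q75 - q25})
    return pd.DataFrame(rows)
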