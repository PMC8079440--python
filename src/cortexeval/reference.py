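"""Brute-force reference computations used to validate the samplers.

These are deliberately independent of the Gibbs implementation in
:mod:`cortexeval.lme`: the random intercepts and the population mean are
integrated out analytically (everything is Gaussian given the scales) and
the remaining two-dimensional posterior over (tau, sigma) is evaluated on a
dense grid. Feasible only for tiny instances; used by the test-suite and the
acceptance script as an oracle, never as the production path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _marginal_loglik(y_by_subject: list[np.ndarray], tau: float, sigma: float,
                     mean_prior_sd: float) -> float:
    """log p(y | tau, sigma) for the intercept-only hierarchical model.

    With a_i ~ N(alpha0, tau^2) and alpha0 ~ N(0, mean_prior_sd^2) both
    integrated out, the stacked data are N(0, Sigma) with
    Sigma = blockdiag(sigma^2 I + tau^2 J) + mean_prior_sd^2 * 1 1^T.
    Evaluated through an explicit Cholesky factorization (the matrix can be
    severely ill-conditioned near the sigma -> 0 grid edge).
    """
    sizes = [len(yi) for yi in y_by_subject]
    n = sum(sizes)
    cov = np.full((n, n), mean_prior_sd**2)
    pos = 0
    for m in sizes:
        cov[pos:pos + m, pos:pos + m] += np.full((m, m), tau**2)
        cov[pos:pos + m, pos:pos + m] += np.eye(m) * sigma**2
        pos += m
    y = np.concatenate(y_by_subject)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        return -np.inf
    w = np.linalg.solve(chol, y)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return float(-0.5 * (n * np.log(2 * np.pi) + logdet + w @ w))


def _log_half_cauchy(s: np.ndarray, scale: float) -> np.ndarray:
    return -np.log1p((s / scale) ** 2)  # unnormalized


def grid_posterior_medians(y_by_subject: list[np.ndarray],
                           cauchy_scale: float = 5.0,
                           mean_prior_sd: float = 10.0,
                           tau_grid: np.ndarray | None = None,
                           sigma_grid: np.ndarray | None = None,
                           n_grid: int = 300) -> tuple[float, float]:
    """Marginal posterior medians of (tau, sigma) by 2-D grid integration.

    The default tau grid extends well past the data scale: with few subjects
    the tau posterior inherits a heavy half-Cauchy right tail and a
    truncated grid biases the median low.
    """
    pooled_sd = float(np.std(np.concatenate(y_by_subject)))
    if tau_grid is None:
        tau_grid = np.linspace(1e-4, max(8.0 * pooled_sd, 2.0), n_grid)
    if sigma_grid is None:
        sigma_grid = np.linspace(1e-4, max(4.0 * pooled_sd, 1.0), n_grid)

    logp = np.empty((len(tau_grid), len(sigma_grid)))
    for i, tau in enumerate(tau_grid):
        for j, sig in enumerate(sigma_grid):
            logp[i, j] = _marginal_loglik(y_by_subject, tau, sig, mean_prior_sd)
    logp += _log_half_cauchy(tau_grid, cauchy_scale)[:, None]
    logp += _log_half_cauchy(sigma_grid, cauchy_scale)[None, :]

    post = np.exp(logp - logp.max())
    post *= np.gradient(tau_grid)[:, None] * np.gradient(sigma_grid)[None, :]
    post /= post.sum()
    tau_median = _grid_median(tau_grid, post.sum(axis=1))
    sigma_median = _grid_median(sigma_grid, post.sum(axis=0))
    return tau_median, sigma_median


def _grid_median(grid: np.ndarray, weights: np.ndarray) -> float:
    cdf = np.cumsum(weights) / weights.sum()
    return float(np.interp(0.5, cdf, grid))


def intercept_posterior_closed_form(data: pd.DataFrame, tau: float,
                                    sigma: float, mean_prior_sd: float = 10.0
                                    ) -> tuple[float, float]:
    """Exact posterior mean and sd of the population intercept alpha0 for the
    intercept-only model with known (tau, sigma).

    Each subject mean ybar_i is N(alpha0, tau^2 + sigma^2/n_i); combined with
    the N(0, mean_prior_sd^2) prior this gives a conjugate Normal posterior.
    """
    grp = data.groupby("subject_id")["y"]
    ybar = grp.mean().to_numpy()
    n_i = grp.size().to_numpy()
    prec_i = 1.0 / (tau**2 + sigma**2 / n_i)
    prec = prec_i.sum() + 1.0 / mean_prior_sd**2
    mean = float(np.sum(prec_i * ybar) / prec)
    return mean, float(1.0 / np.sqrt(prec))
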