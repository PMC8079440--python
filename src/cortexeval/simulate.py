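"""Synthetic regional-thickness cohort generation.

Generates tidy tables with the statistical structure the downstream
evaluations assume: multi-site cross-sectional lifespan cohorts, a
three-group longitudinal cohort with subject-level random intercepts and
slopes, same-day scan-rescan pairs, and paired "pipeline A vs pipeline B"
measurement variants differing only in added bias and noise.

All tables are tidy pandas DataFrames, one row per observation, with the
covariate columns followed by the 62 regional thickness columns in
:data:`cortexeval.regions.REGION_CODES` order. Thickness is clipped to stay
strictly positive; the number of clipped cells is recorded in
``table.attrs["n_clipped"]``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import rng_for
from .config import CohortConfig
from .errors import ConfigurationError
from .regions import N_REGIONS, REGION_CODES

COVARIATE_COLUMNS = [
    "subject_id", "site", "visit_time_months", "gender",
    "age_baseline", "icv", "diagnosis", "apoe",
]

# P(apoe4 allele count = 0, 1, 2 | diagnosis); carriers are enriched in the
# impaired groups, as in elderly memory-clinic cohorts.
_APOE_PROBS = {
    "CN": (0.72, 0.25, 0.03),
    "LMCI": (0.47, 0.43, 0.10),
    "AD": (0.35, 0.48, 0.17),
    "none": (0.72, 0.25, 0.03),
}

_MIN_THICKNESS = 1e-3  # mm; positivity floor for clipping


def _clip_positive(values: np.ndarray) -> tuple[np.ndarray, int]:
    n_clipped = int(np.sum(values < _MIN_THICKNESS))
    return np.maximum(values, _MIN_THICKNESS), n_clipped


def _draw_subjects(config: CohortConfig, diagnoses: np.ndarray,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = len(diagnoses)
    lo, hi = config.age_range
    apoe = np.empty(n, dtype=int)
    for dx in np.unique(diagnoses):
        mask = diagnoses == dx
        apoe[mask] = rng.choice(3, size=mask.sum(), p=_APOE_PROBS[str(dx)])
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:05d}" for i in range(n)],
            "site": [f"site{s:02d}" for s in rng.integers(0, config.n_sites, size=n)],
            "gender": rng.integers(0, 2, size=n),  # 0 = female, 1 = male
            "age_baseline": rng.uniform(lo, hi, size=n),
            "icv": np.maximum(rng.normal(config.icv_mean, config.icv_sd, size=n), 1.0),
            "diagnosis": diagnoses,
            "apoe": apoe,
        }
    )


def _assemble(subjects: pd.DataFrame, visit_time: np.ndarray,
              thickness: np.ndarray, subj_index: np.ndarray,
              extra: dict | None = None) -> pd.DataFrame:
    thickness, n_clipped = _clip_positive(thickness)
    base = subjects.iloc[subj_index].reset_index(drop=True)
    table = pd.DataFrame(
        {
            "subject_id": base["subject_id"].to_numpy(),
            "site": base["site"].to_numpy(),
            "visit_time_months": visit_time.astype(float),
            "gender": base["gender"].to_numpy(),
            "age_baseline": base["age_baseline"].to_numpy(),
            "icv": base["icv"].to_numpy(),
            "diagnosis": base["diagnosis"].to_numpy(),
            "apoe": base["apoe"].to_numpy(),
        }
    )
    if extra:
        for k, v in extra.items():
            table[k] = v
    for j, code in enumerate(REGION_CODES):
        table[code] = thickness[:, j]
    table.attrs["n_clipped"] = n_clipped
    table.attrs["gender_coding"] = {"0": "female", "1": "male"}
    return table


def generate_cross_sectional(config: CohortConfig, n_subjects: int,
                             seed: int | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-visit multi-site lifespan cohort.

    Per region k: thickness = alpha0[k] + age_slope[k]*age +
    gender_effect[k]*gender + subject intercept (sd tau[k]) + residual
    (sd sigma[k]). Returns (subjects, visits).
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    rng = rng_for(config.seed if seed is None else seed, "cross_sectional")
    subjects = _draw_subjects(config, np.array(["none"] * n_subjects), rng)

    age = subjects["age_baseline"].to_numpy()[:, None]
    gender = subjects["gender"].to_numpy()[:, None]
    u = rng.normal(0.0, 1.0, size=(n_subjects, N_REGIONS)) * config.tau
    eps = rng.normal(0.0, 1.0, size=(n_subjects, N_REGIONS)) * config.sigma
    thickness = (config.alpha0 + config.age_slope * age
                 + config.gender_effect * gender + u + eps)
    visits = _assemble(subjects, np.zeros(n_subjects), thickness,
                       np.arange(n_subjects))
    return subjects, visits


def generate_longitudinal(config: CohortConfig, seed: int | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Three-group longitudinal cohort with random intercepts and slopes.

    Per subject i and region k: intercept ~ Normal(alpha0[k], tau[k]^2),
    slope ~ Normal(beta0[k] + diagnosis offset, rho[k]^2); observation j adds
    a site intercept (sd ``site_sd``) and Normal(0, sigma[k]^2) residual at
    visit time t (months). A retention probability < 1 truncates schedules
    monotonically (subjects never return after a missed visit).
    """
    schedule = np.asarray(list(config.visit_schedule), dtype=float)
    if schedule.size == 0:
        raise ConfigurationError("visit_schedule must be non-empty")
    rng = rng_for(config.seed if seed is None else seed, "longitudinal")

    diagnoses = np.concatenate(
        [np.repeat(dx, n) for dx, n in config.group_sizes.items()]
    )
    n = len(diagnoses)
    if n == 0:
        raise ConfigurationError("at least one subject required")
    subjects = _draw_subjects(config, diagnoses, rng)

    offsets = np.array([config.diagnosis_slope_offsets.get(dx, 0.0)
                        for dx in diagnoses])[:, None]
    intercepts = config.alpha0 + rng.normal(size=(n, N_REGIONS)) * config.tau
    slopes = (config.beta0 + offsets
              + rng.normal(size=(n, N_REGIONS)) * config.rho)
    site_codes = subjects["site"].astype("category").cat.codes.to_numpy()
    site_effects = rng.normal(0.0, config.site_sd,
                              size=(site_codes.max() + 1, N_REGIONS))

    # monotone dropout: number of visits kept per subject
    n_visits = np.full(n, len(schedule))
    if config.retention < 1.0:
        keep = rng.random(size=(n, len(schedule) - 1)) < config.retention
        dropped = ~np.cumprod(keep, axis=1).astype(bool)
        first_drop = np.where(dropped.any(axis=1),
                              dropped.argmax(axis=1) + 1, len(schedule))
        n_visits = first_drop

    subj_index = np.repeat(np.arange(n), n_visits)
    times = np.concatenate([schedule[:m] for m in n_visits])
    eps = rng.normal(size=(len(times), N_REGIONS)) * config.sigma
    thickness = (intercepts[subj_index]
                 + site_effects[site_codes[subj_index]]
                 + slopes[subj_index] * times[:, None]
                 + eps)
    visits = _assemble(subjects, times, thickness, subj_index)
    return subjects, visits


def generate_scan_rescan(config: CohortConfig, n_subjects: int,
                         seed: int | None = None) -> pd.DataFrame:
    """Two same-day acquisitions per subject sharing the true regional value.

    The two measurements differ only by independent residuals of sd sigma[k];
    the ``acquisition`` column indexes them (1, 2).
    """
    if n_subjects < 2:
        raise ConfigurationError(
            "scan-rescan requires >= 2 subjects (ICC undefined otherwise)")
    rng = rng_for(config.seed if seed is None else seed, "scan_rescan")
    subjects = _draw_subjects(config, np.array(["none"] * n_subjects), rng)
    truth = config.alpha0 + rng.normal(size=(n_subjects, N_REGIONS)) * config.tau

    subj_index = np.repeat(np.arange(n_subjects), 2)
    eps = rng.normal(size=(2 * n_subjects, N_REGIONS)) * config.sigma
    thickness = truth[subj_index] + eps
    table = _assemble(subjects, np.zeros(2 * n_subjects), thickness, subj_index,
                      extra={"acquisition": np.tile([1, 2], n_subjects)})
    return table


def emulate_pipeline_pair(table: pd.DataFrame, config: CohortConfig,
                          seed: int | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired measurement variants of one cohort table.

    Variant A is the input unchanged; variant B adds a constant bias and
    independent Normal(0, pipeline_b_noise_sd^2) noise to every thickness
    cell (clipped to stay positive), emulating a second processing pipeline
    measuring the same anatomy.
    """
    if len(table) == 0:
        raise ConfigurationError("input table is empty")
    rng = rng_for(config.seed if seed is None else seed, "pipeline_pair")
    table_a = table.copy()
    table_b = table.copy()
    values = table[list(REGION_CODES)].to_numpy(dtype=float)
    noisy = (values + config.pipeline_b_bias
             + rng.normal(size=values.shape) * config.pipeline_b_noise_sd)
    noisy, n_clipped = _clip_positive(noisy)
    table_b[list(REGION_CODES)] = noisy
    table_b.attrs["n_clipped"] = n_clipped
    table_a.attrs.setdefault("n_clipped", 0)
    return table_a, table_b
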