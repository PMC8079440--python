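"""Configuration objects for cohort synthesis and model fitting.

Units are stated explicitly because they are easy to get wrong:

* visit time is in **months** since baseline, so population and per-subject
  slopes are in **mm/month**;
* ages are in years; intracranial volume (ICV) in mm^3; thickness in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._utils import as_region_array
from .errors import ConfigurationError
from .regions import DKT_REGIONS, N_REGIONS

# Plausible adult regional mean thicknesses (mm) for the 31 DKT labels; the
# entorhinal cortex is the thickest, and the default adds a small rightward
# asymmetry there so a single reference cell exists in relative-thickness
# tables. These are generator defaults, not estimates from any cohort.
_BASE_THICKNESS = {
    "cACC": 2.85, "cMFG": 2.65, "CUN": 1.95, "ENT": 3.60, "FUS": 2.80,
    "IPL": 2.55, "ITG": 2.85, "iCC": 2.45, "LOG": 2.20, "LOF": 2.70,
    "LING": 2.05, "MOF": 2.50, "MTG": 2.95, "PARH": 2.90, "paraC": 2.45,
    "pOPER": 2.70, "pORB": 2.75, "pTRI": 2.60, "periCAL": 1.70,
    "postC": 2.10, "PCC": 2.50, "preC": 2.60, "PCUN": 2.40, "rACC": 2.95,
    "rMFG": 2.55, "SFG": 2.75, "SPL": 2.25, "STG": 2.90, "SMAR": 2.60,
    "TT": 2.45, "INS": 3.05,
}
_RH_ASYMMETRY = {"ENT": 0.02}


def default_alpha0() -> np.ndarray:
    """Default per-region population intercepts (mm), in region order."""
    vals = []
    for r in DKT_REGIONS:
        v = _BASE_THICKNESS[r.abbreviation]
        if r.hemisphere == "right":
            v += _RH_ASYMMETRY.get(r.abbreviation, 0.0)
        vals.append(v)
    return np.array(vals)


@dataclass
class CohortConfig:
    """Generative parameters for synthetic thickness cohorts.

    The longitudinal generator draws, per subject i and region k,
    an intercept ~ Normal(alpha0[k], tau[k]^2) and a slope
    ~ Normal(beta0[k] + diagnosis offset, rho[k]^2); observations add
    Normal(0, sigma[k]^2) residuals and an optional site intercept.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"CN": 197, "LMCI": 324, "AD": 142}
    )
    visit_schedule: Sequence[float] = (0, 6, 12, 18, 24, 30, 36)
    n_sites: int = 12
    age_range: tuple[float, float] = (4.0, 94.0)
    # per-region generative parameters; scalars broadcast over the 62 regions
    alpha0: object = field(default_factory=default_alpha0)   # mm
    beta0: object = -0.0005                                   # mm/month
    tau: object = 0.25                                        # mm, between-subject
    rho: object = 0.002                                       # mm/month, slope sd
    sigma: object = 0.08                                      # mm, residual
    age_slope: object = -0.004                                # mm/year (cross-sectional)
    gender_effect: object = 0.02                              # mm added for gender==1
    diagnosis_slope_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 0.0, "LMCI": -0.001, "AD": -0.0025}
    )
    site_sd: float = 0.02          # mm, site random intercept (longitudinal)
    retention: float = 1.0         # per-visit probability of remaining in study
    icv_mean: float = 1.5e6        # mm^3
    icv_sd: float = 1.5e5          # mm^3
    pipeline_b_bias: float = 0.02      # mm, systematic offset of variant B
    pipeline_b_noise_sd: float = 0.05  # mm, extra measurement noise of variant B
    seed: int = 0

    def __post_init__(self) -> None:
        self.alpha0 = as_region_array(self.alpha0, N_REGIONS, "alpha0")
        self.beta0 = as_region_array(self.beta0, N_REGIONS, "beta0")
        self.tau = as_region_array(self.tau, N_REGIONS, "tau")
        self.rho = as_region_array(self.rho, N_REGIONS, "rho")
        self.sigma = as_region_array(self.sigma, N_REGIONS, "sigma")
        self.age_slope = as_region_array(self.age_slope, N_REGIONS, "age_slope")
        self.gender_effect = as_region_array(self.gender_effect, N_REGIONS, "gender_effect")
        self.validate()

    def validate(self) -> None:
        for name in ("tau", "rho", "sigma"):
            if np.any(getattr(self, name) < 0):
                raise ConfigurationError(f"{name} must be non-negative")
        if self.site_sd < 0 or self.pipeline_b_noise_sd < 0:
            raise ConfigurationError("variance-scale parameters must be non-negative")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be non-negative")
        sched = list(self.visit_schedule)
        if not sched:
            raise ConfigurationError("visit_schedule must be non-empty")
        if sched[0] != 0 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ConfigurationError("visit_schedule must increase strictly from 0")
        lo, hi = self.age_range
        if not (0 <= lo < hi):
            raise ConfigurationError("age_range must be a positive increasing pair")
        if not (0.0 <= self.retention <= 1.0):
            raise ConfigurationError("retention must be in [0, 1]")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        d["group_sizes"] = dict(self.group_sizes)
        d["visit_schedule"] = list(self.visit_schedule)
        return d

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "age_range" in data:
            data["age_range"] = tuple(data["age_range"])
        return cls(**data)


def adni_like_config(**overrides) -> CohortConfig:
    """A longitudinal-cohort configuration mirroring an elderly three-group study
    (197 CN / 324 LMCI / 142 AD, 6-monthly visits to 36 months, baseline ages 55-90)."""
    params = dict(age_range=(55.0, 90.0))
    params.update(overrides)
    return CohortConfig(**params)


@dataclass
class PriorConfig:
    """Priors of the hierarchical thickness model: Normal(0, mean_prior_sd^2) on the
    population intercept/slope, half-Cauchy(0, cauchy_scale) on sigma, tau, rho."""

    mean_prior_sd: float = 10.0
    cauchy_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.mean_prior_sd <= 0 or self.cauchy_scale <= 0:
            raise ConfigurationError("prior scales must be positive")


@dataclass
class McmcConfig:
    n_chains: int = 4
    n_iterations: int = 2000   # total per chain, including warmup
    n_warmup: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ConfigurationError("n_chains must be >= 2")
        if not (1 <= self.n_warmup < self.n_iterations):
            raise ConfigurationError("need n_iterations > n_warmup >= 1")
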