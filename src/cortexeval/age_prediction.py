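"""Monte-Carlo cross-validated age prediction from regional thickness.

A random-forest regression of the form

    AGE ~ ICV + GENDER + T(region_1) + ... + T(region_62)

is refit on repeated random 80/20 train/test splits (stratified by
site/dataset label); the root-mean-square error between predicted and actual
age on each held-out fold is the figure of merit. Lower mean RMSE means the
thickness measurements carry more age-related signal relative to noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from ._utils import derive_seed
from .errors import ConfigurationError, SchemaError
from .regions import REGION_CODES

_MIN_SUBJECTS = 25
_MIN_TEST = 5


@dataclass
class AgePredictionResult:
    dataset: str
    pipeline: str
    rmse_per_permutation: np.ndarray = field(repr=False)
    rmse_mean: float = 0.0

    def __post_init__(self):
        self.rmse_per_permutation = np.asarray(self.rmse_per_permutation, float)
        self.rmse_mean = float(np.mean(self.rmse_per_permutation))


class AgePredictionHarness(BaseEstimator):
    """Repeated train/test evaluation of a random-forest age model.

    Parameters
    ----------
    n_permutations : int
        Number of independent Monte-Carlo train/test resplits (default 500).
    train_fraction : float
        Fraction of subjects in each training fold (default 0.8).
    n_trees : int
        Forest size (default 500, default feature subsampling).
    seed : int
        Master seed; each permutation derives its own split/forest seed, and
        splits are keyed to sorted subject ids, so row order is irrelevant.

    After ``fit(table)`` the attributes ``rmse_per_permutation_`` and
    ``rmse_mean_`` (years) hold the evaluation result.
    """

    def __init__(self, n_permutations: int = 500, train_fraction: float = 0.8,
                 n_trees: int = 500, seed: int = 0):
        self.n_permutations = n_permutations
        self.train_fraction = train_fraction
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, table: pd.DataFrame, y=None) -> "AgePredictionHarness":
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be >= 1")
        needed = ["subject_id", "site", "age_baseline", "icv", "gender",
                  *REGION_CODES]
        missing = [c for c in needed if c not in table.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing[:5]}")
        table = table.sort_values("subject_id").reset_index(drop=True)
        if len(table) < _MIN_SUBJECTS:
            raise ConfigurationError(
                f"need >= {_MIN_SUBJECTS} subjects, got {len(table)}")
        n_test = int(round(len(table) * (1 - self.train_fraction)))
        if n_test < _MIN_TEST:
            raise ConfigurationError("fewer than 5 test subjects per split")

        features = table[["icv", "gender", *REGION_CODES]].to_numpy(float)
        age = table["age_baseline"].to_numpy(float)
        if not np.isfinite(features).all() or not np.isfinite(age).all():
            raise SchemaError("non-finite covariate or age values")
        strata = table["site"].to_numpy()
        # stratification needs every site in both folds; fall back when rare
        counts = pd.Series(strata).value_counts()
        stratify = strata if counts.min() >= 2 and counts.size > 1 else None

        rmse = np.empty(self.n_permutations)
        index = np.arange(len(table))
        for p in range(self.n_permutations):
            seed_p = derive_seed(self.seed, "permutation", p)
            tr, te = train_test_split(
                index, train_size=self.train_fraction,
                random_state=seed_p % (2**32 - 1), stratify=stratify)
            forest = RandomForestRegressor(
                n_estimators=self.n_trees, random_state=seed_p % (2**32 - 1),
                n_jobs=1)
            forest.fit(features[tr], age[tr])
            pred = forest.predict(features[te])
            rmse[p] = float(np.sqrt(np.mean((pred - age[te]) ** 2)))

        self.rmse_per_permutation_ = rmse
        self.rmse_mean_ = float(rmse.mean())
        return self

    def result(self, dataset: str = "combined",
               pipeline: str = "A") -> AgePredictionResult:
        return AgePredictionResult(dataset, pipeline,
                                   self.rmse_per_permutation_)


def run_age_prediction(table: pd.DataFrame, n_permutations: int = 500,
                       train_fraction: float = 0.8, n_trees: int = 500,
                       seed: int = 0, dataset: str = "combined",
                       pipeline: str = "A") -> AgePredictionResult:
    """Functional wrapper over :class:`AgePredictionHarness`."""
    harness = AgePredictionHarness(n_permutations, train_fraction,
                                   n_trees, seed).fit(table)
    return harness.result(dataset, pipeline)


def compare_pipeline_rmse(res_a: AgePredictionResult,
                          res_b: AgePredictionResult) -> dict:
    """Paired permutation-matched comparison of two pipelines' RMSE vectors."""
    if res_a.dataset != res_b.dataset:
        raise ConfigurationError(
            f"dataset labels differ: {res_a.dataset!r} vs {res_b.dataset!r}")
    if len(res_a.rmse_per_permutation) != len(res_b.rmse_per_permutation):
        raise ConfigurationError("permutation counts differ")
    diffs = res_b.rmse_per_permutation - res_a.rmse_per_permutation
    return {
        "dataset": res_a.dataset,
        "pipeline_a": res_a.pipeline,
        "pipeline_b": res_b.pipeline,
        "rmse_mean_a": res_a.rmse_mean,
        "rmse_mean_b": res_b.rmse_mean,
        "mean_difference": float(diffs.mean()),
        "paired_differences": diffs,
    }
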