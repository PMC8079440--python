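"""Lifespan regional thickness models and relative-thickness (radar) tables.

Per region, ordinary least squares of thickness on gender and age:

    T(region) ~ GENDER + AGE

The fitted models predict thickness at representative ages (25, 50, 75
years) for each gender; plotting values are expressed relative to the single
maximum predicted thickness across every (pipeline, region, age, gender)
cell, so the radar table lies in (0, 1] with exactly one reference cell.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, SchemaError
from .regions import DKT_REGIONS, REGION_CODES

_HEMI = {r.code: r.hemisphere for r in DKT_REGIONS}


class LifespanThicknessModel(BaseEstimator):
    """Per-region OLS of thickness on gender (0/1) and age (years).

    After ``fit(table)``, ``coefficients_`` is a DataFrame indexed by region
    with columns intercept (mm), gender (mm) and age (mm/year), and
    ``age_range_`` records the fitted age span (predictions outside it warn
    but proceed).
    """

    def fit(self, table: pd.DataFrame, y=None) -> "LifespanThicknessModel":
        missing = [c for c in ("age_baseline", "gender", *REGION_CODES)
                   if c not in table.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing[:5]}")
        if len(table) < 10:
            raise ConfigurationError("need >= 10 subjects")
        age = table["age_baseline"].to_numpy(float)
        gender = table["gender"].to_numpy(float)
        if np.unique(age).size < 2 and np.unique(gender).size < 2:
            raise ConfigurationError(
                "rank-deficient design: single age and single gender")
        design = sm.add_constant(np.column_stack([gender, age]))
        rows = {}
        self.models_ = {}
        for code in REGION_CODES:
            res = sm.OLS(table[code].to_numpy(float), design).fit()
            rows[code] = res.params
            self.models_[code] = res
        self.coefficients_ = pd.DataFrame.from_dict(
            rows, orient="index", columns=["intercept", "gender", "age"]
        ).loc[list(REGION_CODES)]
        self.age_range_ = (float(age.min()), float(age.max()))
        return self

    def predict(self, age: float, gender: int) -> pd.Series:
        """Predicted thickness (mm) per region at one (age, gender)."""
        lo, hi = self.age_range_
        if not (lo <= age <= hi):
            warnings.warn(f"age {age} outside fitted range [{lo:.1f}, {hi:.1f}]; "
                          "extrapolating", stacklevel=2)
        c = self.coefficients_
        return c["intercept"] + c["gender"] * gender + c["age"] * age


def fit_lifespan_models(table: pd.DataFrame) -> LifespanThicknessModel:
    return LifespanThicknessModel().fit(table)


def predict_relative_thickness(models_per_pipeline: dict[str, LifespanThicknessModel],
                               ages=(25.0, 50.0, 75.0),
                               genders=(0, 1)) -> pd.DataFrame:
    """Radar table of predicted thickness relative to the global maximum.

    One row per (pipeline, region, age, gender); ``relative_value`` divides
    every prediction by the single largest predicted thickness across all
    cells, and ``is_reference`` marks that cell.
    """
    if not models_per_pipeline:
        raise ConfigurationError("need at least one fitted pipeline")
    rows = []
    for label, model in models_per_pipeline.items():
        for age in ages:
            for g in genders:
                pred = model.predict(age, g)
                for code in REGION_CODES:
                    rows.append({
                        "pipeline": label, "region": code,
                        "hemisphere": _HEMI[code], "age": age, "gender": g,
                        "predicted_mm": float(pred[code]),
                    })
    out = pd.DataFrame(rows)
    max_idx = out["predicted_mm"].idxmax()
    out["relative_value"] = out["predicted_mm"] / out.loc[max_idx, "predicted_mm"]
    out["is_reference"] = False
    out.loc[max_idx, "is_reference"] = True
    return out


def paired_region_ttest(pred_a: pd.DataFrame, pred_b: pd.DataFrame
                        ) -> tuple[float, float, int]:
    """Paired two-sided t-test on matched predicted thickness cells.

    Inputs are radar tables (or any frames with region/age/gender and
    ``predicted_mm``); cells are matched on (region, age, gender). A
    zero-variance difference is a degenerate case: p = 1 when the common
    difference is 0, else the p -> 0 limit with a warning.
    """
    keys = ["region", "age", "gender"]
    merged = pred_a.merge(pred_b, on=keys, suffixes=("_a", "_b"))
    if len(merged) < 3:
        raise ConfigurationError("need >= 3 matched cells")
    d = (merged["predicted_mm_a"] - merged["predicted_mm_b"]).to_numpy(float)
    n = len(d)
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return 0.0, 1.0, n - 1
        warnings.warn("zero-variance nonzero paired differences; p -> 0 limit",
                      stacklevel=2)
        return float(np.sign(d.mean()) * np.inf), 0.0, n - 1
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    return t, p, n - 1
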