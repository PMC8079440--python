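"""Supervised longitudinal evaluation: baseline-change mixed models,
pairwise diagnostic contrasts, and false-discovery-rate adjustment.

Per region, the change in thickness from baseline is modeled as

    dY ~ Y_bl + AGE_bl + ICV_bl + APOE_bl + GENDER + DIAGNOSIS_bl
         + VISIT:DIAGNOSIS_bl + (1 | subject) + (1 | site)

fitted by REML. The VISIT:DIAGNOSIS_bl interaction gives one change
trajectory slope per diagnostic group (mm/month); the three pairwise
group differences (LMCI-CN, AD-LMCI, AD-CN) are tested with Tukey
(studentized-range) multiplicity handling within the triple, and
Benjamini-Hochberg FDR is applied across the 62 regions within each
contrast. Subjects are nested within acquisition sites, so the crossed
(1|ID) + (1|SITE) structure is fitted as a site random intercept with
subject variance components inside sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, SchemaError
from .regions import DKT_REGIONS, REGION_CODES

logger = logging.getLogger(__name__)

DIAGNOSIS_LEVELS = ("CN", "LMCI", "AD")
CONTRASTS = ("LMCI-CN", "AD-LMCI", "AD-CN")
_LOG10_FLOOR = 1e-300
_HEMI = {r.code: r.hemisphere for r in DKT_REGIONS}


# --------------------------------------------------------------- prepare

def prepare_delta(table: pd.DataFrame) -> pd.DataFrame:
    """Long baseline-change table: one row per (subject, follow-up visit,
    region).

    dY = Y(visit) - Y(0); baseline covariates are attached from the month-0
    visit. Subjects without a baseline visit are excluded (count logged and
    recorded in ``attrs["n_excluded_no_baseline"]``).
    """
    missing = [c for c in ("subject_id", "site", "visit_time_months",
                           "diagnosis", *REGION_CODES)
               if c not in table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing[:5]}")
    base = table[table["visit_time_months"] == 0]
    follow = table[table["visit_time_months"] > 0]
    if follow.empty:
        raise ConfigurationError("table has no follow-up visits")
    has_bl = set(base["subject_id"])
    excluded = sorted(set(table["subject_id"]) - has_bl)
    if excluded:
        logger.warning("excluding %d subjects without baseline: %s...",
                       len(excluded), excluded[:5])
        follow = follow[follow["subject_id"].isin(has_bl)]

    bl = base.set_index("subject_id")
    merged = follow.merge(
        bl[list(REGION_CODES)].add_suffix("_bl"),
        left_on="subject_id", right_index=True, how="inner")

    region_delta = (merged[list(REGION_CODES)].to_numpy(float)
                    - merged[[f"{c}_bl" for c in REGION_CODES]].to_numpy(float))
    y_bl = merged[[f"{c}_bl" for c in REGION_CODES]].to_numpy(float)
    n = len(merged)
    out = pd.DataFrame({
        "subject_id": np.repeat(merged["subject_id"].to_numpy(), len(REGION_CODES)),
        "site": np.repeat(merged["site"].to_numpy(), len(REGION_CODES)),
        "region": np.tile(np.array(REGION_CODES), n),
        "delta_y": region_delta.ravel(),
        "y_bl": y_bl.ravel(),
        "age_bl": np.repeat(merged["age_baseline"].to_numpy(float), len(REGION_CODES)),
        "icv_bl": np.repeat(merged["icv"].to_numpy(float), len(REGION_CODES)),
        "apoe_bl": np.repeat(merged["apoe"].to_numpy(float), len(REGION_CODES)),
        "gender": np.repeat(merged["gender"].to_numpy(float), len(REGION_CODES)),
        "diagnosis_bl": np.repeat(merged["diagnosis"].to_numpy(), len(REGION_CODES)),
        "visit": np.repeat(merged["visit_time_months"].to_numpy(float), len(REGION_CODES)),
    })
    out.attrs["n_excluded_no_baseline"] = len(excluded)
    return out


# ------------------------------------------------------------------- fit

@dataclass
class FittedContrastModel:
    """A fitted per-region baseline-change mixed model plus metadata."""

    result: object            # statsmodels MixedLMResults
    slope_params: dict        # diagnosis level -> fixed-effect name
    df_resid: float
    boundary_fit: bool
    region: str = ""


def fit_contrast_model(delta: pd.DataFrame, visit: str = "continuous",
                       region: str = "") -> FittedContrastModel:
    """Fit the baseline-change mixed model for one region's delta table.

    ``visit="continuous"`` (months, default) estimates one trajectory slope
    per diagnostic group; ``"categorical"`` fits per-visit group terms and
    contrasts their average.
    """
    levels = set(delta["diagnosis_bl"].unique())
    missing_levels = [lv for lv in DIAGNOSIS_LEVELS if lv not in levels]
    if missing_levels:
        raise ConfigurationError(
            f"missing diagnosis level(s): {', '.join(missing_levels)}")
    if delta["site"].nunique() < 2:
        raise ConfigurationError("need >= 2 sites for a site random intercept")
    per_group = delta.groupby("diagnosis_bl")["subject_id"].nunique()
    if per_group.min() < 2:
        raise ConfigurationError("need >= 2 subjects per diagnosis group")

    data = delta.copy()
    data["diagnosis_bl"] = pd.Categorical(
        data["diagnosis_bl"], categories=list(DIAGNOSIS_LEVELS))
    data["icv_bl_Ml"] = data["icv_bl"] / 1e6  # megalitre-scale ICV for conditioning

    if visit == "continuous":
        interaction = "visit:C(diagnosis_bl)"
    elif visit == "categorical":
        interaction = "C(visit):C(diagnosis_bl)"
    else:
        raise ConfigurationError(f"unknown visit coding {visit!r}")
    formula = ("delta_y ~ y_bl + age_bl + icv_bl_Ml + apoe_bl + gender "
               f"+ C(diagnosis_bl) + {interaction}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["site"],
                            re_formula="1",
                            vc_formula={"subject": "0 + C(subject_id)"})
        result = model.fit(reml=True, method=["lbfgs", "powell"])

    # boundary: site or subject variance collapsed to ~0
    site_var = float(np.asarray(result.cov_re)[0, 0])
    subj_var = float(result.vcomp[0]) if len(result.vcomp) else 0.0
    scale = float(result.scale)
    boundary = (site_var < 1e-8 * max(scale, 1e-12)
                or subj_var < 1e-8 * max(scale, 1e-12)
                or not result.converged)

    names = list(result.params.index)
    slope_params: dict[str, list[str]] = {lv: [] for lv in DIAGNOSIS_LEVELS}
    for name in names:
        if "visit" not in name or ":" not in name:
            continue
        for lv in DIAGNOSIS_LEVELS:
            if f"[{lv}]" in name or f"[T.{lv}]" in name:
                slope_params[lv].append(name)
    if any(not v for v in slope_params.values()):
        raise RuntimeError(f"could not locate trajectory terms in {names}")

    k_fe = len(result.fe_params)
    df_resid = float(len(data) - k_fe)
    return FittedContrastModel(result, slope_params, df_resid, boundary, region)


def tukey_diagnostic_contrasts(model: FittedContrastModel) -> list[dict]:
    """Pairwise trajectory-term contrasts with Tukey multiplicity handling.

    Returns one dict per contrast (LMCI-CN, AD-LMCI, AD-CN) with the
    estimate (mm/month) and the studentized-range p-value at k = 3 groups
    and the model's residual degrees of freedom.
    """
    res = model.result
    params = res.params
    cov = res.cov_params()
    names = list(params.index)

    def level_vector(level: str) -> np.ndarray:
        cols = model.slope_params[level]
        vec = np.zeros(len(names))
        for c in cols:  # average across visit levels in the categorical coding
            vec[names.index(c)] = 1.0 / len(cols)
        return vec

    pairs = {"LMCI-CN": ("LMCI", "CN"), "AD-LMCI": ("AD", "LMCI"),
             "AD-CN": ("AD", "CN")}
    out = []
    for label in CONTRASTS:
        hi, lo = pairs[label]
        lvec = level_vector(hi) - level_vector(lo)
        est = float(lvec @ params.to_numpy())
        se = float(np.sqrt(lvec @ cov.to_numpy() @ lvec))
        if se == 0.0:
            p = 1.0 if est == 0.0 else 0.0
        else:
            q = abs(est / se) * np.sqrt(2.0)
            p = float(studentized_range.sf(q, 3, model.df_resid))
        out.append({"contrast": label, "estimate": est, "p_raw": min(max(p, 0.0), 1.0),
                    "boundary_fit": model.boundary_fit})
    return out


# ------------------------------------------------------------------- FDR

def fdr_adjust(results: pd.DataFrame, family: str = "contrast") -> pd.DataFrame:
    """Benjamini-Hochberg adjustment of raw p-values.

    ``family="contrast"`` (default) applies the step-up across the 62
    regions separately within each contrast; ``"global"`` pools all tests
    into one family. Adds ``p_fdr`` and ``log10_p_fdr`` (floored at 1e-300).
    """
    p = results["p_raw"].to_numpy(float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    out = results.copy()
    if family == "contrast":
        adjusted = np.empty(len(out))
        for _, idx in out.groupby("contrast", sort=False).groups.items():
            adjusted[out.index.get_indexer(idx)] = multipletests(
                out.loc[idx, "p_raw"].to_numpy(float), method="fdr_bh")[1]
    elif family == "global":
        adjusted = multipletests(p, method="fdr_bh")[1]
    else:
        raise ConfigurationError(f"unknown FDR family {family!r}")
    out["p_fdr"] = adjusted
    out["log10_p_fdr"] = np.log10(np.maximum(adjusted, _LOG10_FLOOR))
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values for one family (thin statsmodels wrapper)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ------------------------------------------------------------ full sweep

class LongitudinalContrastAnalysis(BaseEstimator):
    """End-to-end diagnostic-contrast evaluation of one pipeline's table.

    ``fit(table)`` runs prepare_delta -> per-region mixed-model fit ->
    Tukey contrasts -> per-contrast BH-FDR, leaving ``results_`` as a
    62 x 3-row frame (region, hemisphere, contrast, estimate, p_raw, p_fdr,
    log10_p_fdr, boundary_fit_flag).
    """

    def __init__(self, visit: str = "continuous", fdr_family: str = "contrast"):
        self.visit = visit
        self.fdr_family = fdr_family

    def fit(self, table: pd.DataFrame, y=None) -> "LongitudinalContrastAnalysis":
        delta = prepare_delta(table)
        rows = []
        for code in REGION_CODES:
            sub = delta[delta["region"] == code]
            try:
                model = fit_contrast_model(sub, visit=self.visit, region=code)
            except ConfigurationError:
                raise
            except Exception as exc:
                raise RuntimeError(f"region {code}: {exc}") from exc
            for rec in tukey_diagnostic_contrasts(model):
                rows.append({"region": code, "hemisphere": _HEMI[code], **rec})
        frame = pd.DataFrame(rows).rename(
            columns={"boundary_fit": "boundary_fit_flag"})
        self.results_ = fdr_adjust(frame, family=self.fdr_family)
        self.n_excluded_no_baseline_ = delta.attrs["n_excluded_no_baseline"]
        return self


def run_longitudinal_evaluation(table: pd.DataFrame, visit: str = "continuous",
                                fdr_family: str = "contrast") -> pd.DataFrame:
    """Functional wrapper over :class:`LongitudinalContrastAnalysis`."""
    return LongitudinalContrastAnalysis(visit, fdr_family).fit(table).results_
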