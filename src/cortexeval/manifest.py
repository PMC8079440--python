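"""Run manifests and end-to-end orchestration of all evaluation stages.

A manifest (YAML) names the stages to run, the cohort and model settings,
the pipeline labels and the output directory. Every artifact is a plain CSV
or JSON file; the written ``manifest.json`` records the resolved
configuration, master seed, package version and a content checksum for each
output, so a rerun with the same manifest reproduces every file byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .age_prediction import compare_pipeline_rmse, run_age_prediction
from .config import CohortConfig, McmcConfig, adni_like_config
from .contrasts import run_longitudinal_evaluation
from .errors import ConfigurationError
from .icc import compute_icc, icc_frame
from .io import write_table
from .lifespan import fit_lifespan_models, paired_region_ttest, predict_relative_thickness
from .lme import fit_all_regions, posterior_summary_frame, summarize_pipelines
from .simulate import (
    emulate_pipeline_pair,
    generate_cross_sectional,
    generate_longitudinal,
    generate_scan_rescan,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "pipelines", "age-predict", "lifespan-radar", "icc",
          "variance-ratio", "longitudinal-eval")

_DEFAULTS = {
    "seed": 0,
    "output_dir": "cortexeval_out",
    "stages": list(STAGES),
    "pipelines": ["A", "B"],
    "cohort": {},             # longitudinal / rescan cohort overrides
    "cross_cohort": {},       # cross-sectional cohort overrides
    "cross_sectional_n": 300,
    "rescan_n": 60,
    "age_prediction": {"n_permutations": 50, "n_trees": 200},
    "mcmc": {"n_chains": 2, "n_iterations": 800, "n_warmup": 300},
    "visit_coding": "continuous",
    "fdr_family": "contrast",
}


def load_manifest(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return resolve_manifest(user)


def resolve_manifest(user: dict | None = None) -> dict:
    manifest = {k: (v.copy() if isinstance(v, (dict, list)) else v)
                for k, v in _DEFAULTS.items()}
    for k, v in (user or {}).items():
        if k not in manifest:
            raise ConfigurationError(f"unknown manifest key {k!r}")
        if isinstance(manifest[k], dict) and isinstance(v, dict):
            manifest[k].update(v)
        else:
            manifest[k] = v
    unknown = [s for s in manifest["stages"] if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stage(s): {unknown}")
    if len(manifest["pipelines"]) != 2:
        raise ConfigurationError("exactly two pipeline labels expected")
    return manifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_evaluation(manifest: dict) -> Path:
    """Execute the requested stages and return the output directory.

    Stages build on simulate/pipelines outputs held in memory; a failing
    stage raises with its name while earlier files stay on disk.
    """
    manifest = resolve_manifest(manifest)
    seed = int(manifest["seed"])
    out = Path(manifest["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    label_a, label_b = manifest["pipelines"]
    stages = manifest["stages"]
    outputs: list[Path] = []
    state: dict = {}

    def save(frame: pd.DataFrame, name: str) -> None:
        path = out / name
        write_table(frame, path)
        outputs.append(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, default=_jsonable))
        outputs.append(path)

    for stage in stages:
        logger.info("stage %s", stage)
        try:
            if stage == "simulate":
                long_cfg = adni_like_config(seed=derive_seed(seed, "long"),
                                            **manifest["cohort"])
                cross_cfg = CohortConfig(seed=derive_seed(seed, "cross"),
                                         **manifest["cross_cohort"])
                _, state["cross"] = generate_cross_sectional(
                    cross_cfg, int(manifest["cross_sectional_n"]))
                _, state["long"] = generate_longitudinal(long_cfg)
                state["rescan"] = generate_scan_rescan(
                    long_cfg, int(manifest["rescan_n"]),
                    seed=derive_seed(seed, "rescan"))
                state["long_cfg"] = long_cfg
                save(state["cross"], "cohort_cross_sectional.csv")
                save(state["long"], "cohort_longitudinal.csv")
                save(state["rescan"], "cohort_scan_rescan.csv")
            elif stage == "pipelines":
                cfg = state["long_cfg"]
                for kind in ("cross", "long", "rescan"):
                    a, b = emulate_pipeline_pair(
                        state[kind], cfg, seed=derive_seed(seed, "pair", kind))
                    state[f"{kind}_{label_a}"] = a
                    state[f"{kind}_{label_b}"] = b
                    save(b, f"cohort_{kind}_{label_b}.csv")
            elif stage == "age-predict":
                ap = manifest["age_prediction"]
                results = {}
                for label in (label_a, label_b):
                    res = run_age_prediction(
                        state[f"cross_{label}"], seed=derive_seed(seed, "age", label),
                        pipeline=label, **ap)
                    results[label] = res
                    save(pd.DataFrame({"permutation": range(len(res.rmse_per_permutation)),
                                       "rmse_years": res.rmse_per_permutation}),
                         f"age_rmse_{label}.csv")
                cmp = compare_pipeline_rmse(results[label_a], results[label_b])
                cmp.pop("paired_differences")
                save_json(cmp, "age_rmse_comparison.json")
            elif stage == "lifespan-radar":
                models = {label: fit_lifespan_models(state[f"cross_{label}"])
                          for label in (label_a, label_b)}
                radar = predict_relative_thickness(models)
                save(radar, "lifespan_radar.csv")
                t, p, df = paired_region_ttest(
                    radar[radar["pipeline"] == label_a],
                    radar[radar["pipeline"] == label_b])
                save_json({"t": t, "p": p, "df": df}, "lifespan_paired_ttest.json")
            elif stage == "icc":
                for label in (label_a, label_b):
                    save(icc_frame(compute_icc(state[f"rescan_{label}"])),
                         f"icc_{label}.csv")
            elif stage == "variance-ratio":
                mc = manifest["mcmc"]
                per_pipeline = {}
                for label in (label_a, label_b):
                    mcmc = McmcConfig(seed=derive_seed(seed, "vr", label), **mc)
                    results = fit_all_regions(state[f"long_{label}"], mcmc=mcmc)
                    per_pipeline[label] = results
                    save(posterior_summary_frame(results),
                         f"variance_ratio_{label}.csv")
                save(summarize_pipelines(per_pipeline), "variance_ratio_summary.csv")
            elif stage == "longitudinal-eval":
                for label in (label_a, label_b):
                    res = run_longitudinal_evaluation(
                        state[f"long_{label}"], visit=manifest["visit_coding"],
                        fdr_family=manifest["fdr_family"])
                    save(res, f"longitudinal_contrasts_{label}.csv")
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    record = {
        "tool": "cortexeval",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "resolved_manifest": {k: v for k, v in manifest.items()},
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(record, indent=2, default=_jsonable))
    return out


def _jsonable(obj):
    try:
        return obj.item()
    except AttributeError:
        return str(obj)
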