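"""Tidy-CSV reading, writing and schema validation for thickness tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .regions import REGION_CODES
from .simulate import COVARIATE_COLUMNS


def write_table(table: pd.DataFrame, path) -> None:
    """Write a cohort table as plain CSV (full float precision, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    """Read a cohort CSV and check its schema; raises SchemaError when invalid."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such table: {path}")
    table = pd.read_csv(path, float_precision="round_trip")
    report = validate_frame(table)
    if not report["valid"]:
        raise SchemaError(f"{path}: " + "; ".join(report["violations"][:5]))
    return table


def validate_frame(table: pd.DataFrame) -> dict:
    """Schema report for an in-memory table.

    Checks the covariate + 62-region column set, thickness positivity and
    finiteness, and uniqueness of the observation key. Returns a
    machine-readable dict with keys ``valid``, ``violations``,
    ``missing_columns``, ``n_rows``.
    """
    violations: list[str] = []
    missing = [c for c in COVARIATE_COLUMNS if c not in table.columns]
    missing += [c for c in REGION_CODES if c not in table.columns]
    for col in missing:
        violations.append(f"missing column {col}")

    present_regions = [c for c in REGION_CODES if c in table.columns]
    if present_regions and len(table):
        values = table[present_regions].to_numpy(dtype=float)
        bad = np.argwhere(~(np.isfinite(values) & (values > 0)))
        for row, col in bad[:50]:
            violations.append(
                f"non-positive or non-finite thickness at row {row}, "
                f"column {present_regions[col]}"
            )

    key_cols = [c for c in ("subject_id", "visit_time_months", "acquisition")
                if c in table.columns]
    if len(key_cols) >= 2 and len(table):
        dup = table.duplicated(subset=key_cols)
        if dup.any():
            violations.append(
                f"duplicate observation key {tuple(key_cols)} in "
                f"{int(dup.sum())} rows (first at row {int(dup.idxmax())})"
            )

    return {
        "valid": not violations,
        "violations": violations,
        "missing_columns": missing,
        "n_rows": int(len(table)),
    }


def validate_table(path) -> dict:
    """Schema report for a CSV file on disk (see validate_frame)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such table: {path}")
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise IOError(f"unreadable table {path}: {exc}") from exc
    report = validate_frame(table)
    report["path"] = str(path)
    return report
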