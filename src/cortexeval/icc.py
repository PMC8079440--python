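"""Scan-rescan repeatability via the intraclass correlation coefficient.

The "average random rater" reading: two-way random-effects, average-measures
ICC — ICC(2,k) — computed per region from the mean squares of the complete
subject x acquisition ANOVA:

    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

with MSR the between-subject, MSC the between-acquisition and MSE the
residual mean square, n subjects and k acquisitions. Values near 1 mean the
averaged acquisitions almost perfectly rank subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError
from .regions import REGION_CODES


@dataclass
class ICCResult:
    region: str
    icc_value: float
    between_subject_var: float
    residual_var: float


def _icc_2k(matrix: np.ndarray) -> tuple[float, float, float]:
    """ICC(2,k) and variance components from an n x k measurement matrix."""
    n, k = matrix.shape
    grand = matrix.mean()
    row_means = matrix.mean(axis=1)
    col_means = matrix.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = matrix - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    icc = 1.0 if denom == 0.0 else (msr - mse) / denom
    between = max((msr - mse) / k, 0.0)
    return float(icc), float(between), float(mse)


def compute_icc(rescan_table: pd.DataFrame) -> list[ICCResult]:
    """Per-region ICC(2,k) from a scan-rescan table.

    The table needs ``subject_id``, an ``acquisition`` index, and the 62
    region columns; the design must be complete (every subject measured in
    every acquisition, exactly once).
    """
    needed = ["subject_id", "acquisition", *REGION_CODES]
    missing = [c for c in needed if c not in rescan_table.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing[:5]}")
    counts = rescan_table.groupby("subject_id")["acquisition"].nunique()
    per_subj = rescan_table.groupby("subject_id").size()
    if per_subj.nunique() != 1 or (counts != per_subj).any():
        raise ConfigurationError(
            "incomplete design: every subject needs the same acquisitions")
    n = len(counts)
    k = int(per_subj.iloc[0])
    if n < 5:
        raise ConfigurationError("need >= 5 subjects for ICC")
    if k < 2:
        raise ConfigurationError("need >= 2 acquisitions per subject")

    wide = rescan_table.sort_values(["subject_id", "acquisition"])
    results = []
    for code in REGION_CODES:
        matrix = wide[code].to_numpy(float).reshape(n, k)
        icc, between, resid = _icc_2k(matrix)
        results.append(ICCResult(code, icc, between, resid))
    return results


def icc_frame(results: list[ICCResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
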