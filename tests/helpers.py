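"""Independent oracles and fixture builders shared by the test suite.

The oracles here are deliberately written in the most literal style
possible (explicit loops, textbook formulas) and never call into
mirqc, so that agreement between an oracle and the implementation is
evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def icc_oracle(x: np.ndarray, definition: str) -> float:
    """Two-way ANOVA single-measure ICC via explicit double loops."""
    n, k = x.shape
    grand = 0.0
    for i in range(n):
        for j in range(k):
            grand += x[i, j]
    grand /= n * k
    row_means = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum(
        (x[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    if definition == "consistency":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return (ms_r - ms_e) / (
        ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    )


def ols_r_squared_oracle(x, y) -> tuple[float, float, float]:
    """Simple-regression slope/intercept/R² from the closed-form sums."""
    n = len(x)
    sx = sum(x)
    sy = sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    sy_mean = sy / n
    sx_mean = sx / n
    num = sum((a - sx_mean) * (b - sy_mean) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - sx_mean) ** 2 for a in x)
        * sum((b - sy_mean) ** 2 for b in y)
    )
    r2 = (num / den) ** 2
    return slope, intercept, r2


WELL_DEFAULTS = {
    "plate_id": "p1",
    "system": "taqman",
    "kit": "Q",
    "assay_id": "miR-16",
    "sample_id": "S01",
    "sample_role": "plasma",
    "rt_replicate": 1,
    "qpcr_replicate": 1,
    "preamplified": True,
    "cq": 25.0,
    "dilution_step": pd.NA,
    "melt_pass": pd.NA,
}


def make_wells(rows: list[dict]) -> pd.DataFrame:
    """Canonical well table from partial row dicts (defaults filled)."""
    full = [{**WELL_DEFAULTS, **row} for row in rows]
    df = pd.DataFrame(full)
    df["dilution_step"] = df["dilution_step"].astype("Int64")
    df["melt_pass"] = df["melt_pass"].astype("boolean")
    df["cq"] = df["cq"].astype(float)
    return df


def make_aggregates(rows: list[dict]) -> pd.DataFrame:
    """Aggregate table from partial row dicts (defaults filled)."""
    defaults = {
        "plate_id": "p1",
        "system": "taqman",
        "kit": "Q",
        "assay_id": "miR-16",
        "sample_id": "S01",
        "sample_role": "plasma",
        "dilution_step": pd.NA,
        "rt_replicate": 1,
        "preamplified": True,
        "cq_avg": 25.0,
        "n_wells_used": 3,
        "n_wells_total": 3,
    }
    df = pd.DataFrame([{**defaults, **row} for row in rows])
    df["dilution_step"] = df["dilution_step"].astype("Int64")
    df["cq_avg"] = df["cq_avg"].astype(float)
    return df
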