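"""Performance metrics for extraction kits and RT-qPCR systems.

* Recovery — per-kit median and CV of the spike-in Cq: a low median
  means the kit recovered more of a known input, a small CV means the
  recovery was even across samples.
* Reproducibility (R1-R3) — ICC (two-way mixed, absolute agreement)
  between technical replicates: RT replicates raw (R1), RT replicates
  after spike-in normalisation (R2), qPCR replicate wells raw (R3).
* Accuracy (A1, A2) — how faithfully the measured Cq difference
  between two standard-curve points reproduces the difference implied
  by the known dilution design (ddCq); negated mean ddCq so that
  higher = better, split into abundant-point pairs (A1) and pairs
  touching a low point (A2).
* Sensitivity (S1, S2) — fraction of determined (non-censored) Cq in
  plasma samples (S1) and titration points (S2).

All scores are oriented so that a higher value means better
performance, and are z-scored across systems for side-by-side display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats
from .errors import InsufficientDataError, ZeroVarianceError

METRIC_FIELDS = ["A1", "A2", "R1", "R2", "R3", "S1", "S2"]


@dataclass(frozen=True)
class StandardDesign:
    """Known layout of the standard dilution series.

    ``fold_per_step`` is the dilution factor between consecutive
    points; ``abundant_steps`` / ``low_steps`` partition the step
    indices into the high-input set and the near-limit set.
    """

    fold_per_step: float = 10.0
    abundant_steps: tuple[int, ...] = (1, 2, 3, 4, 5)
    low_steps: tuple[int, ...] = (6, 7)
    #: optional fitted slope (Cq per log10 input); when set, calculated
    #: deltas use the observed efficiency instead of assuming 100%
    slope: float | None = None

    def calculated_delta(self, step_i: int, step_j: int) -> float:
        """Design-implied Cq difference between two dilution steps.

        Default assumes 100% efficiency (one doubling per cycle, so
        delta Cq = log2 of the input ratio); with ``slope`` set, the
        delta is slope x the log10 input difference.
        """
        if self.slope is not None:
            return (step_j - step_i) * -self.slope * math.log10(
                self.fold_per_step
            )
        return (step_j - step_i) * math.log2(self.fold_per_step)


def recovery_summary(spike_agg: pd.DataFrame) -> pd.DataFrame:
    """Median and CV% of raw spike-in Cq per kit x system x spike assay.

    Groups with fewer than two determined values keep their median but
    have CV omitted (NaN) and are flagged.
    """
    rows = []
    for (kit, system, assay), grp in spike_agg.groupby(
        ["kit", "system", "assay_id"], sort=True
    ):
        vals = grp["cq_avg"].dropna().to_numpy(dtype=float)
        n = vals.size
        if n == 0:
            median = cv = float("nan")
        else:
            median = float(np.median(vals))
            if n >= 2 and vals.mean() != 0:
                cv = 100.0 * float(np.std(vals, ddof=1)) / float(vals.mean())
            else:
                cv = float("nan")
        rows.append(
            {"kit": kit, "system": system, "spike_assay": assay,
             "median_cq": median, "cv_pct": cv, "n": n,
             "cv_omitted": n < 2}
        )
    return pd.DataFrame(rows)


def ddcq(calculated_delta: float, measured_delta: float) -> float:
    """|calculated (Cq point1 - point2) - measured (Cq point1 - point2)|."""
    return abs(calculated_delta - measured_delta)


def accuracy_scores(
    standard_agg: pd.DataFrame, design: StandardDesign,
    adjacent_only: bool = False,
) -> tuple[float, float]:
    """(A1, A2) from a system's standard-curve aggregates.

    Every ordered pair of standard points contributes one ddCq (or
    only adjacent steps with ``adjacent_only``); A1 averages pairs
    within the abundant set, A2 pairs touching at least one low point,
    each negated so 0 is perfect and more negative is worse.  Pairs
    with an undetermined endpoint are skipped; a score with no usable
    pair is NaN.
    """
    abundant = set(design.abundant_steps)
    low = set(design.low_steps)
    dd_a1, dd_a2 = [], []
    for _, grp in standard_agg.groupby("assay_id", sort=True):
        cq = {
            int(s): float(v)
            for s, v in zip(grp["dilution_step"], grp["cq_avg"])
            if pd.notna(v) and pd.notna(s)
        }
        steps = sorted(cq)
        for a_idx, si in enumerate(steps):
            for sj in steps[a_idx + 1:]:
                if adjacent_only and sj - si != 1:
                    continue
                d = ddcq(design.calculated_delta(si, sj), cq[sj] - cq[si])
                if si in abundant and sj in abundant:
                    dd_a1.append(d)
                if si in low or sj in low:
                    dd_a2.append(d)
    a1 = -float(np.mean(dd_a1)) if dd_a1 else float("nan")
    a2 = -float(np.mean(dd_a2)) if dd_a2 else float("nan")
    return a1, a2


def sensitivity_scores(
    censored: pd.DataFrame, cq_ceiling: float = 40.0
) -> tuple[float, float]:
    """(S1, S2): determined fraction in plasma/serum cells and in
    titration points, on already-censored values (a cell at the
    ceiling counts as not detected)."""
    plasma = censored[censored["sample_role"].isin(["plasma", "serum"])]
    titr = censored[censored["sample_role"] == "titration_point"]
    s1 = (
        float((plasma["cq_censored"] < cq_ceiling).mean())
        if len(plasma) else float("nan")
    )
    s2 = (
        float((titr["cq_censored"] < cq_ceiling).mean())
        if len(titr) else float("nan")
    )
    return s1, s2


def _replicate_icc(
    frame: pd.DataFrame, rep_col: str, value_col: str,
    cq_ceiling: float, exclude_censored: bool = True,
) -> float:
    """ICC(A,1) between replicate 1 and 2 of ``rep_col``."""
    index_cols = [c for c in ("kit", "sample_id") if c in frame.columns]
    mats = {}
    for rep in (1, 2):
        sub = frame[frame[rep_col] == rep]
        mats[rep] = sub.pivot_table(
            index=index_cols, columns="assay_id", values=value_col,
            aggfunc="mean", sort=True,
        )
    try:
        pm = _stats.build_paired_matrix(
            mats[1], mats[2],
            exclude_censored=exclude_censored, cq_ceiling=cq_ceiling,
        )
        return _stats.icc_twoway_mixed(pm, "absolute_agreement").icc
    except (InsufficientDataError, ZeroVarianceError):
        return float("nan")


def reproducibility_scores(
    censored: pd.DataFrame,
    normalized: pd.DataFrame,
    wells: pd.DataFrame,
    cq_ceiling: float = 40.0,
) -> tuple[float, float, float]:
    """(R1, R2, R3) for one system's plasma/serum data.

    R1: RT replicate 1 vs 2 on censored (raw-scale) averages;
    R2: same pairs on spike-in-normalised values (censored cells
    excluded via their flag, since after normalisation the floor is no
    longer at the ceiling value);
    R3: qPCR replicate well 1 vs 2, raw, within RT replicate 1.
    """
    bio = censored[censored["sample_role"].isin(["plasma", "serum"])]
    r1 = _replicate_icc(bio, "rt_replicate", "cq_censored", cq_ceiling)

    norm = normalized.copy()
    norm.loc[norm["censored"].astype(bool), "norm_cq"] = np.nan
    r2 = _replicate_icc(norm, "rt_replicate", "norm_cq",
                        cq_ceiling=np.inf)

    w = wells[
        wells["sample_role"].isin(["plasma", "serum"])
        & (wells["rt_replicate"] == 1)
    ]
    r3 = _replicate_icc(w, "qpcr_replicate", "cq", cq_ceiling)
    return r1, r2, r3


def score_table(scores_by_system: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble per-system scores and z-score each metric across systems.

    A metric that is identical across systems (or defined for fewer
    than two) gets NaN z-scores, flagged by the ``z_undefined``
    column listing the affected metrics.
    """
    systems = list(scores_by_system)
    table = pd.DataFrame(
        [{**{"system": s}, **scores_by_system[s]} for s in systems]
    ).set_index("system")
    undefined = []
    for metric in METRIC_FIELDS:
        if metric not in table.columns:
            continue
        vals = table[metric].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if ok.sum() >= 2 and np.std(vals[ok], ddof=1) > 0:
            z = np.full_like(vals, np.nan)
            z[ok] = (vals[ok] - vals[ok].mean()) / np.std(vals[ok], ddof=1)
            table[f"z_{metric}"] = z
        else:
            table[f"z_{metric}"] = np.nan
            undefined.append(metric)
    table["z_undefined"] = ";".join(undefined)
    return table.reset_index()
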