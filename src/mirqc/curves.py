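"""Dilution-curve fitting, linearity QC and detection-limit censoring.

Serial dilutions — of pooled synthetic miRNAs ("standard" curves) or of
pooled cell-line RNA ("titration" curves) — establish the Cq span over
which an assay amplifies linearly.  A straight line of average Cq on
log10 relative input is fitted by ordinary least squares; an assay is
linear when R² ≥ 0.9 over at least three determined points.  Sample Cq
values beyond the high-Cq end of that interpolation range, and wells
that never crossed threshold at all, are below the detection limit and
are censored to the cycle ceiling (40 by default).  Cq values *below*
the low end of the range are unexpectedly concentrated rather than
undetectable, so they pass through unchanged but flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientPointsError

R_SQUARED_LINEAR_MIN = 0.9


@dataclass(frozen=True)
class DilutionSeries:
    """One serial-dilution series for one assay on one system."""

    assay_id: str
    system: str
    source: str  # "synthetic_standard" | "pooled_titration"
    dilution_step: tuple[int, ...]
    log_relative_input: tuple[float, ...]  # log10 units, decreasing
    cq_avg: tuple[float, ...]  # NaN = undetermined


@dataclass(frozen=True)
class CurveFit:
    assay_id: str
    system: str
    source: str
    slope: float  # Cq per log10 input
    intercept: float
    r_squared: float
    n_points_used: int
    interp_cq_min: float
    interp_cq_max: float
    linear: bool
    efficiency: float  # 10**(-1/slope) - 1; reported, never gated on

    @classmethod
    def insufficient(cls, assay_id, system, source, n_points) -> "CurveFit":
        nan = float("nan")
        return cls(assay_id, system, source, nan, nan, nan, n_points,
                   nan, nan, False, nan)


def series_from_aggregates(
    agg: pd.DataFrame, source: str, fold_per_step: float
) -> list[DilutionSeries]:
    """Build one :class:`DilutionSeries` per (assay, system) from
    aggregated dilution-point rows.

    ``fold_per_step`` is the dilution factor between consecutive steps;
    relative input of step ``s`` is ``fold_per_step**-s`` so
    ``log_relative_input = -s * log10(fold_per_step)``.
    """
    role = {"synthetic_standard": "standard_point",
            "pooled_titration": "titration_point"}[source]
    sub = agg[agg["sample_role"] == role]
    out = []
    for (assay, system), grp in sub.groupby(["assay_id", "system"], sort=True):
        grp = grp.sort_values("dilution_step")
        steps = tuple(int(s) for s in grp["dilution_step"])
        out.append(
            DilutionSeries(
                assay_id=assay,
                system=system,
                source=source,
                dilution_step=steps,
                log_relative_input=tuple(
                    -s * math.log10(fold_per_step) for s in steps
                ),
                cq_avg=tuple(float(v) for v in grp["cq_avg"]),
            )
        )
    return out


def fit_dilution_curve(series: DilutionSeries) -> CurveFit:
    """Ordinary least squares of Cq on log10 relative input.

    Only determined points enter the fit; fewer than three of them
    raises :class:`InsufficientPointsError`.  R² is the squared Pearson
    correlation of fitted versus observed Cq, and the interpolation
    range is the span of *observed* Cq among the points used.
    """
    x = np.asarray(series.log_relative_input, dtype=float)
    y = np.asarray(series.cq_avg, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        raise InsufficientPointsError(
            f"{series.assay_id}/{series.system}/{series.source}: "
            f"only {n} determined dilution point(s), need >= 3"
        )
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    linear = bool(n >= 3 and np.isfinite(r2) and r2 >= R_SQUARED_LINEAR_MIN)
    eff = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else float("nan")
    return CurveFit(
        assay_id=series.assay_id,
        system=series.system,
        source=series.source,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_points_used=n,
        interp_cq_min=float(y.min()),
        interp_cq_max=float(y.max()),
        linear=linear,
        efficiency=float(eff),
    )


def fit_all_curves(
    agg: pd.DataFrame,
    fold_per_step: dict[str, float],
) -> dict[tuple[str, str, str], CurveFit]:
    """Fit every dilution series present in the aggregate table.

    ``fold_per_step`` maps source ("synthetic_standard" /
    "pooled_titration") to its dilution factor.  Series with too few
    determined points yield a placeholder fit with ``linear=False``
    (the assay is flagged downstream, never crashed on).
    """
    fits: dict[tuple[str, str, str], CurveFit] = {}
    for source, fold in fold_per_step.items():
        for series in series_from_aggregates(agg, source, fold):
            try:
                fit = fit_dilution_curve(series)
            except InsufficientPointsError:
                n = int(np.isfinite(np.asarray(series.cq_avg)).sum())
                fit = CurveFit.insufficient(
                    series.assay_id, series.system, source, n
                )
            fits[(series.assay_id, series.system, source)] = fit
    return fits


def fits_to_frame(fits) -> pd.DataFrame:
    """Tabulate curve fits, one row per (assay, system, source)."""
    from dataclasses import asdict

    rows = [asdict(f) for f in (fits.values() if isinstance(fits, dict) else fits)]
    return pd.DataFrame(rows)


def censor_to_detection_limit(
    cq_avg: float, fit: CurveFit, cq_ceiling: float = 40.0
) -> float:
    """Censor one aggregate Cq against a linear curve's range.

    Undetermined (NaN) values and values above ``fit.interp_cq_max``
    are below the detection limit and become ``cq_ceiling``; in-range
    values pass through unchanged, as do (flag-worthy) values below
    ``fit.interp_cq_min``.
    """
    if not fit.linear:
        raise ValueError(
            "censoring against a non-linear curve is meaningless; "
            "the assay should have been excluded by QC"
        )
    if isinstance(cq_avg, float) and math.isnan(cq_avg):
        return cq_ceiling
    if cq_avg > fit.interp_cq_max:
        return cq_ceiling
    return float(cq_avg)


def censor_aggregates(
    agg: pd.DataFrame,
    fits: dict[tuple[str, str, str], CurveFit],
    cq_ceiling: float = 40.0,
    prefer_source: str = "pooled_titration",
) -> pd.DataFrame:
    """Apply detection-limit censoring to every plasma/serum, spike-in
    and titration aggregate.

    The interpolation range comes from the assay's ``prefer_source``
    curve when one exists, else from the other source; spike-in assays,
    which have no dilution series of their own, are censored against
    the cycle ceiling only (undetermined -> ceiling).

    Returns a copy with ``cq_censored`` plus ``censored`` and
    ``below_range`` flags.
    """
    other = ({"pooled_titration", "synthetic_standard"} - {prefer_source}).pop()
    out = agg.copy()
    cq = out["cq_avg"].to_numpy(dtype=float)
    censored_val = np.where(np.isnan(cq) | (cq > cq_ceiling), cq_ceiling, cq)
    below = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        fit = fits.get((row.assay_id, row.system, prefer_source)) or fits.get(
            (row.assay_id, row.system, other)
        )
        if fit is None or not fit.linear:
            continue
        v = cq[i]
        if np.isnan(v) or v > fit.interp_cq_max:
            censored_val[i] = cq_ceiling
        elif v < fit.interp_cq_min:
            below[i] = True
    out["cq_censored"] = censored_val
    out["censored"] = censored_val >= cq_ceiling
    out["below_range"] = below
    return out
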