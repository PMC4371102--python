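"""Assay-level quality control: the three exclusion criteria.

An assay is dropped from the analysis when at least one of these holds:

1. non-linear amplification in its titration and/or standard curve
   (coefficient of determination R² < 0.9);
2. undetermined Cq in more than 50% of the plasma/serum samples
   (strict inequality — exactly half does not exclude);
3. failure of melt-curve analysis, for chemistries that use a
   DNA-binding dye.

Melt curves are consumed as per-well pass/fail flags; because the
original judgement was made visually from dissociation plots, the
numeric rule here — fail when any no-template-control well fails or
when more than ``melt_fail_fraction`` of sample wells fail — is a
documented stand-in, with the threshold configurable.

Every assay receives a report, excluded or not, and exclusions carry
machine-readable reason codes so the omission list is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CurveFit
from .errors import ConfigurationError

#: systems whose detection chemistry is a DNA-binding dye (melt QC applies)
DYE_SYSTEMS = {"miscript", "mircury"}

REASON_NONLINEAR = "nonlinear_curve"
REASON_UNDETERMINED = "undetermined_gt_50pct"
REASON_MELT = "melt_failure"
REASON_INSUFFICIENT = "insufficient_curve_points"

#: fraction of failing sample wells beyond which melt QC fails
DEFAULT_MELT_FAIL_FRACTION = 0.2
#: determined NTC within this many cycles of the ceiling does NOT warn
DEFAULT_NTC_MARGIN = 5.0


@dataclass(frozen=True)
class AssayQCReport:
    assay_id: str
    system: str
    included: bool
    reasons: frozenset[str] = field(default_factory=frozenset)
    undetermined_fraction: float = float("nan")
    r_squared_standard: float | None = None
    r_squared_titration: float | None = None
    melt_fail_fraction: float | None = None
    ntc_contamination: bool = False  # warning only, never excludes


def evaluate_assay_qc(
    aggregates: pd.DataFrame,
    fits: list[CurveFit],
    wells: pd.DataFrame | None = None,
    melt_fail_fraction: float = DEFAULT_MELT_FAIL_FRACTION,
    ntc_margin: float = DEFAULT_NTC_MARGIN,
    cq_ceiling: float = 40.0,
) -> AssayQCReport:
    """Run the three exclusion criteria for one (assay, system).

    ``aggregates`` must be restricted to that assay and system and
    contain its plasma/serum rows; ``fits`` are its curve fits (either
    source); ``wells`` supplies per-well melt flags and NTC Cq values
    and is required for DNA-binding-dye systems.
    """
    assay = str(aggregates["assay_id"].iloc[0])
    system = str(aggregates["system"].iloc[0])
    reasons: set[str] = set()

    # criterion 1 — linearity of every available dilution curve
    r2_std = r2_tit = None
    for fit in fits:
        if fit.source == "synthetic_standard":
            r2_std = fit.r_squared
        else:
            r2_tit = fit.r_squared
        if fit.n_points_used < 3:
            reasons.add(REASON_INSUFFICIENT)
        elif not fit.linear:
            reasons.add(REASON_NONLINEAR)

    # criterion 2 — undetermined in more than half of the samples
    bio = aggregates[aggregates["sample_role"].isin(["plasma", "serum"])]
    if len(bio):
        frac = float(bio["cq_avg"].isna().mean())
    else:
        frac = float("nan")
    if np.isfinite(frac) and frac > 0.5:
        reasons.add(REASON_UNDETERMINED)

    # criterion 3 — melt-curve failure (dye chemistries only)
    melt_frac = None
    ntc_warn = False
    if system in DYE_SYSTEMS:
        if wells is None or "melt_pass" not in wells.columns:
            raise ConfigurationError(
                f"{assay}/{system}: melt_pass flags are required for "
                "DNA-binding-dye systems"
            )
        w = wells[(wells["assay_id"] == assay) & (wells["system"] == system)]
        flagged = w[w["melt_pass"].notna()]
        sample_wells = flagged[flagged["sample_role"].isin(["plasma", "serum"])]
        ntc_wells = flagged[flagged["sample_role"] == "ntc"]
        if len(sample_wells):
            melt_frac = float((~sample_wells["melt_pass"].astype(bool)).mean())
            if melt_frac > melt_fail_fraction:
                reasons.add(REASON_MELT)
        if len(ntc_wells) and (~ntc_wells["melt_pass"].astype(bool)).any():
            reasons.add(REASON_MELT)

    # NTC contamination check: warns, never excludes
    if wells is not None:
        ntc = wells[
            (wells["assay_id"] == assay)
            & (wells["system"] == system)
            & (wells["sample_role"] == "ntc")
        ]
        ntc_cq = ntc["cq"].dropna()
        if len(ntc_cq) and (ntc_cq < cq_ceiling - ntc_margin).any():
            ntc_warn = True

    return AssayQCReport(
        assay_id=assay,
        system=system,
        included=not reasons,
        reasons=frozenset(reasons),
        undetermined_fraction=frac,
        r_squared_standard=r2_std,
        r_squared_titration=r2_tit,
        melt_fail_fraction=melt_frac,
        ntc_contamination=ntc_warn,
    )


def evaluate_all_assays(
    aggregates: pd.DataFrame,
    fits: dict[tuple[str, str, str], CurveFit],
    wells: pd.DataFrame | None = None,
    spike_assays: tuple[str, ...] = (),
    **kwargs,
) -> list[AssayQCReport]:
    """One QC report per endogenous (assay, system) in the table.

    Spike-in assays are exempt: they exist to normalise, have no
    dilution series, and are never candidates for exclusion.
    """
    reports = []
    endo = aggregates[~aggregates["assay_id"].isin(spike_assays)]
    endo = endo[endo["sample_role"] != "ntc"]
    for (assay, system), grp in endo.groupby(["assay_id", "system"], sort=True):
        assay_fits = [
            f
            for (a, s, _), f in fits.items()
            if a == assay and s == system
        ]
        reports.append(
            evaluate_assay_qc(grp, assay_fits, wells=wells, **kwargs)
        )
    return reports


def reports_to_frame(reports: list[AssayQCReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "assay_id": r.assay_id,
                "system": r.system,
                "included": r.included,
                "reasons": ";".join(sorted(r.reasons)),
                "undetermined_fraction": r.undetermined_fraction,
                "r_squared_standard": r.r_squared_standard,
                "r_squared_titration": r.r_squared_titration,
                "melt_fail_fraction": r.melt_fail_fraction,
                "ntc_contamination": r.ntc_contamination,
            }
        )
    return pd.DataFrame(rows)


def filter_dataset(
    aggregates: pd.DataFrame, reports: list[AssayQCReport]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded (assay, system) pairs; return (kept, exclusion log).

    The log mirrors a supplementary "assays omitted" listing: one row
    per excluded assay with its reason codes.  Assays without a report
    (spike-ins) are retained.
    """
    excluded = {(r.assay_id, r.system) for r in reports if not r.included}
    mask = [
        (a, s) not in excluded
        for a, s in zip(aggregates["assay_id"], aggregates["system"])
    ]
    kept = aggregates[np.asarray(mask)].reset_index(drop=True)
    log = reports_to_frame([r for r in reports if not r.included])
    if log.empty:
        log = pd.DataFrame(columns=["assay_id", "system", "reasons"])
    else:
        log = log[["assay_id", "system", "reasons"]]
    return kept, log.reset_index(drop=True)
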