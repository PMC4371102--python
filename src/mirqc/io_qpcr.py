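"""Reading, writing and replicate aggregation of long-format Cq tables.

One row of a long table is one qPCR well: the raw quantification cycle
(Cq) plus its full experimental coordinates (plate, RT-qPCR system,
extraction kit, assay, sample, replicate indices, sample role).  Wells
whose fluorescence never crossed threshold carry an "undetermined"
token; internally these are represented as NaN in the ``cq`` column —
the single missing sentinel of the pipeline — and are only ever turned
into a numeric ceiling by the explicit detection-limit censoring step
(:mod:`mirqc.curves`), never here.

Replicate wells of the same reaction (qPCR replicates) are averaged
into one Cq per (plate, system, kit, assay, sample, RT replicate);
RT replicates are deliberately NOT pooled, because RT-level and
qPCR-level repeatability are analysed as separate axes downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ParseError

#: canonical column order of a well table
REQUIRED_COLUMNS = [
    "plate_id",
    "system",
    "kit",
    "assay_id",
    "sample_id",
    "sample_role",
    "rt_replicate",
    "qpcr_replicate",
    "preamplified",
    "cq",
]
OPTIONAL_COLUMNS = ["dilution_step", "melt_pass", "well_position"]

SAMPLE_ROLES = {
    "plasma",
    "serum",
    "spike_in",
    "standard_point",
    "titration_point",
    "ntc",
}

#: grouping keys of a replicate aggregate: everything well-level removed
AGGREGATE_KEYS = [
    "plate_id",
    "system",
    "kit",
    "assay_id",
    "sample_id",
    "sample_role",
    "dilution_step",
    "rt_replicate",
    "preamplified",
]


@dataclass(frozen=True)
class Dialect:
    """How a delimited Cq export maps onto the canonical well schema.

    Parameters
    ----------
    column_map:
        Mapping from file column names to canonical names; identity for
        canonical files.
    undetermined_tokens:
        Cell values (case-insensitive, stripped) read as "undetermined".
    sep:
        Field separator.
    cq_decimals:
        Decimal places used when writing Cq, so that a written table
        re-reads bit-identically.
    """

    column_map: dict[str, str] = field(default_factory=dict)
    undetermined_tokens: tuple[str, ...] = ("undetermined", "999", "")
    sep: str = ","
    cq_decimals: int = 4
    undetermined_out: str = "Undetermined"


DEFAULT_DIALECT = Dialect()


def read_cq_table(path, dialect: Dialect = DEFAULT_DIALECT) -> pd.DataFrame:
    """Read a long-format well table into the canonical schema.

    Returns one row per well with ``cq`` as float (NaN = undetermined).
    Raises :class:`FormatError` if a required column is missing and
    :class:`ParseError` (with the 1-based file line number) for a Cq
    cell that is neither numeric nor a declared undetermined token.
    """
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    if dialect.column_map:
        df = df.rename(columns=dialect.column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")

    tokens = {t.lower() for t in dialect.undetermined_tokens}
    cq = np.empty(len(df), dtype=float)
    for i, raw in enumerate(df["cq"].tolist()):
        text = raw.strip()
        if text.lower() in tokens:
            cq[i] = np.nan
            continue
        try:
            cq[i] = float(text)
        except ValueError:
            # +2: one for the header line, one for 1-based numbering
            raise ParseError(
                f"non-numeric Cq value {text!r} at line {i + 2}", line=i + 2
            ) from None
    out = df.copy()
    out["cq"] = cq
    for col in ("rt_replicate", "qpcr_replicate"):
        out[col] = out[col].astype(int)
    out["preamplified"] = _parse_bool(out["preamplified"])
    if "dilution_step" in out.columns:
        step = out["dilution_step"].where(out["dilution_step"] != "", np.nan)
        out["dilution_step"] = pd.to_numeric(step).astype("Int64")
    if "melt_pass" in out.columns:
        out["melt_pass"] = _parse_bool(out["melt_pass"], allow_missing=True)
    bad_roles = set(out["sample_role"]) - SAMPLE_ROLES
    if bad_roles:
        raise FormatError(f"unknown sample_role value(s): {sorted(bad_roles)}")
    key_cols = [c for c in (
        "plate_id", "system", "kit", "assay_id", "sample_id",
        "rt_replicate", "qpcr_replicate", "well_position",
    ) if c in out.columns]
    dup = out.duplicated(subset=key_cols)
    if dup.any():
        first = int(dup.idxmax()) + 2
        raise FormatError(
            f"duplicate well at line {first}: key {key_cols} must be unique"
        )
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in out.columns]
    return out[cols]


def _parse_bool(series: pd.Series, allow_missing: bool = False) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    if allow_missing:
        mapping[""] = pd.NA

    def conv(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if v is pd.NA or (isinstance(v, float) and math.isnan(v)):
            return pd.NA
        key = str(v).strip().lower()
        if key not in mapping:
            raise ParseError(f"cannot parse boolean value {v!r}")
        return mapping[key]

    return series.map(conv).astype("boolean" if allow_missing else bool)


def write_long_table(
    wells: pd.DataFrame, path, dialect: Dialect = DEFAULT_DIALECT
) -> None:
    """Write wells back to delimited text, round-trippable via
    :func:`read_cq_table` (Cq rendered at ``dialect.cq_decimals``)."""
    out = wells.copy()
    out["cq"] = [
        dialect.undetermined_out
        if (isinstance(v, float) and math.isnan(v))
        else f"{v:.{dialect.cq_decimals}f}"
        for v in out["cq"]
    ]
    if "melt_pass" in out.columns:
        out["melt_pass"] = out["melt_pass"].map(
            lambda v: "" if pd.isna(v) else str(bool(v))
        )
    if "dilution_step" in out.columns:
        out["dilution_step"] = out["dilution_step"].map(
            lambda v: "" if pd.isna(v) else str(int(v))
        )
    out.to_csv(path, sep=dialect.sep, index=False)


def aggregate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Average qPCR replicate wells into one Cq per reaction.

    Undetermined wells are omitted from the mean; a group in which every
    well is undetermined yields an undetermined (NaN) ``cq_avg`` with
    ``n_wells_used == 0``.  RT replicates stay separate rows.
    """
    if wells.empty:
        raise FormatError("aggregate_wells: empty well table")
    keys = [k for k in AGGREGATE_KEYS if k in wells.columns]
    grouped = wells.groupby(keys, dropna=False, sort=True, observed=True)["cq"]
    agg = grouped.agg(
        cq_avg="mean", n_wells_used="count", n_wells_total="size"
    ).reset_index()
    agg["n_wells_used"] = agg["n_wells_used"].astype(int)
    agg["n_wells_total"] = agg["n_wells_total"].astype(int)
    return agg
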