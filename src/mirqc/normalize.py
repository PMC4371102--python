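"""Spike-in normalisation of censored Cq values.

Exogenous C. elegans miRNAs (cel-miR-39 and cel-miR-54 by default) are
spiked into every sample before extraction, so their measured Cq
absorbs whatever the extraction recovered or lost for that particular
tube.  Subtracting each sample's mean spike-in Cq from its endogenous
Cq values therefore cancels per-sample extraction bias; adding back a
batch-level anchor (the grand mean of the per-sample spike-in means,
by default) keeps the result on the familiar Cq scale, lower = more
abundant.  Samples in which no spike-in was determined cannot be
normalised and are masked with a logged reason, never imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ZeroVarianceError

DEFAULT_SPIKE_ASSAYS = ("cel-miR-39", "cel-miR-54")

#: a sample is one physical tube: same plate, system, kit, RT replicate
SAMPLE_KEYS = ["plate_id", "system", "kit", "rt_replicate", "preamplified",
               "sample_id"]


def normalize_to_spikeins(
    censored: pd.DataFrame,
    spike_assays: tuple[str, ...] = DEFAULT_SPIKE_ASSAYS,
    anchor: float | str = "auto",
    value_col: str = "cq_censored",
    roles: tuple[str, ...] = ("plasma", "serum"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalise endogenous Cq to the per-sample spike-in mean.

    For sample X and assay a:

        normCq(X, a) = cq(X, a) - mean(cq(X, spike-ins)) + anchor

    ``anchor="auto"`` uses the grand mean of the per-sample spike-in
    means of this batch; any real number (e.g. 0 for a pure delta-Cq)
    may be passed instead.  A sample with only one determined spike-in
    falls back to that one (flagged ``n_spikes_used=1``); with none it
    is masked and listed in the returned mask log.

    Returns ``(normalised rows, mask log)``.
    """
    keys = [k for k in SAMPLE_KEYS if k in censored.columns]
    spikes = censored[censored["assay_id"].isin(spike_assays)]
    # a spike-in is usable only when actually determined (not censored-in)
    usable = spikes[spikes["cq_avg"].notna()]
    spike_mean = (
        usable.groupby(keys, sort=False)[value_col]
        .agg(spike_mean="mean", n_spikes_used="size")
        .reset_index()
    )
    if anchor == "auto":
        anchor_val = float(spike_mean["spike_mean"].mean()) if len(spike_mean) else 0.0
    else:
        anchor_val = float(anchor)

    endo = censored[
        censored["sample_role"].isin(roles)
        & ~censored["assay_id"].isin(spike_assays)
    ]
    merged = endo.merge(spike_mean, on=keys, how="left")
    masked = merged[merged["spike_mean"].isna()]
    mask_log = (
        masked[keys].drop_duplicates().assign(reason="no_determined_spike_in")
        if len(masked)
        else pd.DataFrame(columns=keys + ["reason"])
    )
    out = merged[merged["spike_mean"].notna()].copy()
    out["norm_cq"] = out[value_col] - out["spike_mean"] + anchor_val
    out["n_spikes_used"] = out["n_spikes_used"].astype(int)
    out.attrs["anchor"] = anchor_val
    return out.reset_index(drop=True), mask_log.reset_index(drop=True)


def pivot_matrix(
    norm: pd.DataFrame, value_col: str = "norm_cq"
) -> pd.DataFrame:
    """Samples x assays matrix (NaN where a cell is missing/masked)."""
    return norm.pivot_table(
        index="sample_id", columns="assay_id", values=value_col,
        aggfunc="mean", sort=True,
    )


def zscore(values, ddof: int = 1) -> np.ndarray:
    """Standard-score a vector: (x - mean) / sd, sd with ``n - ddof``.

    NaNs pass through; at least two determined values with nonzero
    spread are required, else :class:`ZeroVarianceError`.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ZeroVarianceError("z-score needs >= 2 determined values")
    sd = float(np.std(x[ok], ddof=ddof))
    if sd == 0.0:
        raise ZeroVarianceError("z-score undefined on a constant vector")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def fold_change_over_detection_limit(
    norm_cq, highest_detected_linear_cq: float
):
    """Log2-fold abundance above the detection floor.

    ``highest detected Cq in linear amplification  -  normalised Cq``;
    positive = above the limit, negative values arise only from
    censored (floor-assigned) inputs and should be read as below-limit.
    """
    return highest_detected_linear_cq - np.asarray(norm_cq, dtype=float)
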