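"""Agreement and difference statistics.

Intraclass correlation under the two-way mixed model, in both flavours
used for technical-replication work:

* *consistency* — systematic offsets between raters (kits, systems,
  replicates, time points) are forgiven; appropriate when asking "do
  two conditions rank and space the samples the same way?"
* *absolute agreement* — offsets count against the correlation;
  appropriate for reproducibility of the same protocol on the same
  samples.

Both are the single-measure forms derived from the two-way ANOVA mean
squares (MS_R between subjects, MS_C between raters, MS_E residual):

    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E))

with significance from F = MS_R / MS_E on (n-1, (n-1)(k-1)) df.

Pairing rule: only subjects (sample x assay cells) with determined
values on every rater enter the matrix; incomplete cells are dropped
and counted.  Values censored to the cycle ceiling are an assigned
floor, not a measurement, and are excluded by default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, ZeroVarianceError


@dataclass(frozen=True)
class PairedMatrix:
    """Complete-case subjects x raters value matrix."""

    values: np.ndarray  # (n_subjects, k), no missing values
    subjects: tuple  # identifiers of retained rows
    dropped_incomplete: int

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    model: str  # "twoway_mixed"
    definition: str  # "absolute_agreement" | "consistency"
    f_value: float
    df1: float
    df2: float
    p_value: float
    n: int
    k: int


@dataclass(frozen=True)
class PairedTTestResult:
    t: float
    df: int
    p_two_tailed: float
    mean_diff: float
    n: int
    zero_variance: bool = False


def build_paired_matrix(
    a: pd.DataFrame,
    b: pd.DataFrame,
    exclude_censored: bool = True,
    cq_ceiling: float = 40.0,
) -> PairedMatrix:
    """Align two samples-x-assays matrices into complete pairs.

    ``a`` and ``b`` are pivoted matrices (rows samples, columns
    assays).  Cells missing on either side — NaN, or at/above the
    ceiling when ``exclude_censored`` — are dropped and counted in
    ``dropped_incomplete``.  Fewer than 3 complete pairs raises
    :class:`InsufficientDataError`.
    """
    samples = a.index.union(b.index)
    assays = a.columns.union(b.columns)
    av = a.reindex(index=samples, columns=assays).to_numpy(dtype=float)
    bv = b.reindex(index=samples, columns=assays).to_numpy(dtype=float)
    if exclude_censored:
        av = np.where(av >= cq_ceiling, np.nan, av)
        bv = np.where(bv >= cq_ceiling, np.nan, bv)
    ok = np.isfinite(av) & np.isfinite(bv)
    n_cells = int(np.isfinite(av).sum() + np.isfinite(bv).sum() - ok.sum())
    # a cell counts as a subject; incomplete = observed somewhere but not both
    subjects = [
        (s, m) for (s, m), keep in zip(
            ((s, m) for s in samples for m in assays), ok.ravel()
        ) if keep
    ]
    vals = np.column_stack([av.ravel()[ok.ravel()], bv.ravel()[ok.ravel()]])
    dropped = n_cells - len(subjects)
    if len(subjects) < 3:
        raise InsufficientDataError(
            f"only {len(subjects)} complete pair(s); ICC needs >= 3"
        )
    return PairedMatrix(values=vals, subjects=tuple(subjects),
                        dropped_incomplete=dropped)


def icc_twoway_mixed(
    data, definition: str = "absolute_agreement", average: bool = False
) -> ICCResult:
    """Two-way mixed ICC from the ANOVA decomposition.

    ``data`` is a subjects x raters array (or :class:`PairedMatrix`).
    Single-measure forms by default (the reliability of one
    measurement, which a two-rater technical-replication design
    implies); ``average=True`` gives the average-measure forms
    ICC(C,k) / ICC(A,k).
    """
    if isinstance(data, PairedMatrix):
        x = data.values
    else:
        x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise InsufficientDataError(
            f"ICC needs an n>=3 by k>=2 matrix, got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise InsufficientDataError("ICC matrix must be complete (no NaN)")
    if definition not in ("absolute_agreement", "consistency"):
        raise ValueError(f"unknown ICC definition {definition!r}")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((x - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if ss_total == 0.0:
        raise ZeroVarianceError("ICC undefined on a constant matrix")

    if average:
        if definition == "consistency":
            denom = ms_r
        else:
            denom = ms_r + (ms_c - ms_e) / n
    elif definition == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    icc = (ms_r - ms_e) / denom if denom != 0 else float("nan")

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_e == 0.0:
        f, p = float("inf"), 0.0
    else:
        f = ms_r / ms_e
        p = float(sps.f.sf(f, df1, df2))
    return ICCResult(
        icc=float(icc), model="twoway_mixed", definition=definition,
        f_value=f, df1=float(df1), df2=float(df2), p_value=p, n=n, k=k,
    )


def paired_t_test(x, y) -> PairedTTestResult:
    """Two-tailed paired Student t-test (t on the differences)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    d = x[ok] - y[ok]
    n = d.size
    if n < 2:
        raise InsufficientDataError("paired t-test needs >= 2 complete pairs")
    sd = float(np.std(d, ddof=1))
    mean = float(d.mean())
    if sd == 0.0:
        # all differences identical: degenerate but well-signed
        if mean == 0.0:
            return PairedTTestResult(0.0, n - 1, 1.0, 0.0, n, True)
        t = float(np.inf) if mean > 0 else float(-np.inf)
        return PairedTTestResult(t, n - 1, 0.0, mean, n, True)
    res = sps.ttest_rel(x[ok], y[ok])
    return PairedTTestResult(
        t=float(res.statistic), df=n - 1, p_two_tailed=float(res.pvalue),
        mean_diff=mean, n=n,
    )


def pairwise_agreement(
    matrices: dict[str, pd.DataFrame],
    definition: str = "consistency",
    exclude_censored: bool = True,
    cq_ceiling: float = 40.0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], ICCResult]]:
    """All-pairs ICC across named conditions.

    ``matrices`` maps condition label to a samples-x-assays matrix.
    Returns the symmetric ICC table (diagonal 1 by convention, NaN
    where a pair had insufficient complete data) plus the full
    :class:`ICCResult` per off-diagonal pair.
    """
    if len(matrices) < 2:
        raise InsufficientDataError("pairwise agreement needs >= 2 conditions")
    labels = list(matrices)
    table = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    results: dict[tuple[str, str], ICCResult] = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            try:
                pm = build_paired_matrix(
                    matrices[la], matrices[lb],
                    exclude_censored=exclude_censored, cq_ceiling=cq_ceiling,
                )
                res = icc_twoway_mixed(pm, definition)
                table.loc[la, lb] = table.loc[lb, la] = res.icc
                results[(la, lb)] = res
            except (InsufficientDataError, ZeroVarianceError):
                table.loc[la, lb] = table.loc[lb, la] = np.nan
    return table, results
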