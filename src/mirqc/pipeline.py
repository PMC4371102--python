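"""End-to-end orchestration: wells in, benchmark tables out.

Runs the full evaluation in method order — ingest/simulate, replicate
aggregation, curve fitting, assay QC, detection-limit censoring,
spike-in normalisation, recovery/reproducibility/accuracy/sensitivity
scoring, pairwise agreement, paired comparisons — and accounts for
every input well in exactly one of four tallies:

* ``assay_excluded`` — the well's assay failed QC on its system;
* ``undetermined_omitted`` — the well never crossed threshold;
* ``pair_incomplete`` — determined, but its aggregate was censored to
  the floor or its tube lacked a usable spike-in, so it entered no
  paired statistic;
* ``used`` — contributed to at least one analysis.

Outputs are plain CSV tables plus a JSON run manifest; a structured
run log records one line per QC decision so the "assays omitted"
listing stays greppable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import curves, io_qpcr, metrics, normalize, qc, stats
from .errors import ConfigurationError, InsufficientDataError, ZeroVarianceError
from .io_qpcr import DEFAULT_DIALECT, Dialect
from .metrics import StandardDesign
from .normalize import DEFAULT_SPIKE_ASSAYS
from .synthetic import SimulationConfig, scenario_presets, simulate_study


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serialised into the manifest."""

    preset: str | None = None
    sim: SimulationConfig | None = None
    input_path: str | None = None
    dialect: Dialect = DEFAULT_DIALECT
    seed: int = 0
    spike_assays: tuple[str, ...] = DEFAULT_SPIKE_ASSAYS
    cq_ceiling: float = 40.0
    anchor: float | str = "auto"
    standard_design: StandardDesign = field(default_factory=StandardDesign)
    titration_fold: float = 8.0
    melt_fail_fraction: float = qc.DEFAULT_MELT_FAIL_FRACTION
    ntc_margin: float = qc.DEFAULT_NTC_MARGIN
    kit_icc_definition: str = "consistency"
    out_dir: str | None = None
    plots: bool = False  # optional figures; CSVs stay the canonical output


@dataclass
class PipelineResult:
    status: str  # "ok" | "no_assays_passed_qc"
    wells: pd.DataFrame
    aggregates: pd.DataFrame
    curve_fits: pd.DataFrame
    qc_report: pd.DataFrame
    excluded: pd.DataFrame
    recovery: pd.DataFrame
    censored: pd.DataFrame
    normalized: pd.DataFrame
    icc_pairwise: pd.DataFrame
    replicates_icc: pd.DataFrame
    scores: pd.DataFrame
    paired_tests: pd.DataFrame
    tally: dict[str, int]
    anchor: float
    log: list[str]


def _parse_plate(plate: str) -> tuple[str | None, str | None]:
    """plate_id "{system}-t{tp}-{specimen}" -> (time point, specimen)."""
    parts = plate.split("-")
    if len(parts) == 3 and parts[1].startswith("t"):
        return parts[1], parts[2]
    return None, None


def _resolve_config(cfg: RunConfig) -> tuple[pd.DataFrame, RunConfig]:
    if cfg.sim is None and cfg.preset is not None:
        presets = scenario_presets()
        if cfg.preset not in presets:
            raise ConfigurationError(
                f"unknown preset {cfg.preset!r}; "
                f"choose from {sorted(presets)}"
            )
        cfg.sim = presets[cfg.preset]
    if cfg.sim is not None:
        wells, _ = simulate_study(cfg.sim, seed=cfg.seed)
        cfg.spike_assays = cfg.sim.spike_assays
        cfg.cq_ceiling = cfg.sim.cq_ceiling
        cfg.standard_design = cfg.sim.standard
        cfg.titration_fold = cfg.sim.titration.fold_per_step
    elif cfg.input_path is not None:
        wells = io_qpcr.read_cq_table(cfg.input_path, cfg.dialect)
    else:
        raise ConfigurationError("RunConfig needs a preset, sim or input_path")
    return wells, cfg


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full evaluation; deterministic given config and seed."""
    wells, cfg = _resolve_config(cfg)
    log: list[str] = [
        f"seed={cfg.seed} ceiling={cfg.cq_ceiling} "
        f"melt_fail_fraction={cfg.melt_fail_fraction} "
        f"ntc_margin={cfg.ntc_margin} anchor={cfg.anchor} "
        f"kit_icc_definition={cfg.kit_icc_definition}",
        f"input wells: {len(wells)}",
    ]

    agg = io_qpcr.aggregate_wells(wells)
    fits = curves.fit_all_curves(
        agg,
        {
            "synthetic_standard": cfg.standard_design.fold_per_step,
            "pooled_titration": cfg.titration_fold,
        },
    )
    reports = qc.evaluate_all_assays(
        agg, fits, wells=wells, spike_assays=cfg.spike_assays,
        melt_fail_fraction=cfg.melt_fail_fraction,
        ntc_margin=cfg.ntc_margin, cq_ceiling=cfg.cq_ceiling,
    )
    for r in reports:
        verdict = "included" if r.included else (
            "EXCLUDED " + ",".join(sorted(r.reasons))
        )
        log.append(f"qc {r.assay_id}/{r.system}: {verdict}")
    kept_agg, excluded_log = qc.filter_dataset(agg, reports)
    excluded_pairs = {
        (r.assay_id, r.system) for r in reports if not r.included
    }

    recovery = metrics.recovery_summary(
        kept_agg[
            kept_agg["assay_id"].isin(cfg.spike_assays)
            & (kept_agg["sample_role"] == "spike_in")
        ]
    )

    censored = curves.censor_aggregates(
        kept_agg, fits, cq_ceiling=cfg.cq_ceiling
    )
    norm, mask_log = normalize.normalize_to_spikeins(
        censored, spike_assays=cfg.spike_assays, anchor=cfg.anchor
    )
    anchor = float(norm.attrs.get("anchor", np.nan)) if len(norm) else float("nan")
    for row in mask_log.itertuples(index=False):
        log.append(f"masked sample (no determined spike-in): {tuple(row)}")

    n_endo_included = len(
        {(a, s) for a, s in zip(kept_agg["assay_id"], kept_agg["system"])
         if a not in cfg.spike_assays}
    )
    status = "ok" if n_endo_included else "no_assays_passed_qc"
    if status != "ok":
        log.append("no assays passed QC")

    tp_col = [_parse_plate(p) for p in norm["plate_id"]] if len(norm) else []
    if len(norm):
        norm = norm.assign(
            time_point=[t for t, _ in tp_col],
            specimen=[s for _, s in tp_col],
        )

    icc_rows = []
    rep_rows = []
    scores_by_system: dict[str, dict[str, float]] = {}
    systems = sorted(wells["system"].unique())
    for system in systems:
        cen_s = censored[
            (censored["system"] == system)
            & censored["sample_role"].isin(["plasma", "serum"])
            & ~censored["assay_id"].isin(cfg.spike_assays)
        ]
        norm_s = norm[norm["system"] == system] if len(norm) else norm
        # pairwise kit agreement, raw then normalised, first condition only
        kits = sorted(k for k in cen_s["kit"].unique())
        if len(kits) >= 2:
            first_plate = sorted(cen_s["plate_id"].unique())[0]
            for phase, frame, val in (
                ("raw", cen_s, "cq_censored"),
                ("normalized", norm_s, "norm_cq"),
            ):
                sub = frame[frame["plate_id"] == first_plate]
                if phase == "normalized" and len(sub):
                    sub = sub.copy()
                    sub.loc[sub["censored"].astype(bool), val] = np.nan
                mats = {
                    k: g.pivot_table(index="sample_id", columns="assay_id",
                                     values=val, aggfunc="mean", sort=True)
                    for k, g in sub.groupby("kit")
                }
                if len(mats) < 2:
                    continue
                ceiling = cfg.cq_ceiling if phase == "raw" else np.inf
                _, results = stats.pairwise_agreement(
                    mats, definition=cfg.kit_icc_definition,
                    cq_ceiling=ceiling,
                )
                for (ka, kb), res in results.items():
                    icc_rows.append(
                        {"system": system, "phase": phase, "kit_a": ka,
                         "kit_b": kb, "icc": res.icc, "p_value": res.p_value,
                         "n": res.n}
                    )
        # replicate reproducibility + accuracy + sensitivity
        r1, r2, r3 = metrics.reproducibility_scores(
            cen_s, norm_s, wells[wells["system"] == system],
            cq_ceiling=cfg.cq_ceiling,
        )
        std_s = kept_agg[
            (kept_agg["system"] == system)
            & (kept_agg["sample_role"] == "standard_point")
        ]
        a1, a2 = metrics.accuracy_scores(std_s, cfg.standard_design)
        sens_frame = censored[
            (censored["system"] == system)
            & ~censored["assay_id"].isin(cfg.spike_assays)
        ]
        s1, s2 = metrics.sensitivity_scores(sens_frame, cfg.cq_ceiling)
        rep_rows.append({"system": system, "R1": r1, "R2": r2, "R3": r3})
        scores_by_system[system] = {
            "A1": a1, "A2": a2, "R1": r1, "R2": r2, "R3": r3,
            "S1": s1, "S2": s2,
        }
    replicates_icc = pd.DataFrame(rep_rows)
    scores = (
        metrics.score_table(scores_by_system)
        if len(scores_by_system) >= 2
        else pd.DataFrame(
            [{"system": s, **v} for s, v in scores_by_system.items()]
        )
    )

    paired_tests = _paired_comparisons(norm, cfg)

    tally = _well_tally(wells, censored, mask_log, excluded_pairs, cfg)
    log.append(f"tally: {tally}")

    result = PipelineResult(
        status=status,
        wells=wells,
        aggregates=agg,
        curve_fits=curves.fits_to_frame(fits),
        qc_report=qc.reports_to_frame(reports),
        excluded=excluded_log,
        recovery=recovery,
        censored=censored,
        normalized=norm,
        icc_pairwise=pd.DataFrame(
            icc_rows,
            columns=["system", "phase", "kit_a", "kit_b", "icc", "p_value", "n"],
        ),
        replicates_icc=replicates_icc,
        scores=scores,
        paired_tests=paired_tests,
        tally=tally,
        anchor=anchor,
        log=log,
    )
    if cfg.out_dir is not None:
        _write_bundle(result, cfg)
    return result


COMPARISON_COLUMNS = ["comparison", "assay_id", "t", "df", "p_two_tailed",
                      "mean_diff", "icc_consistency", "icc_p", "n_pairs"]


def _paired_comparisons(norm: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Paired t-tests + consistency ICC across time points and across
    specimen types, on normalised values (censored cells out).

    Each comparison is reported per assay (the unit at which fold
    change is biologically interpreted; the paired differences within
    one assay are independent across individuals) and pooled across
    all sample x assay cells (``assay_id = "pooled"``).  Pooled cells
    of one tube share the tube's spike-in measurement noise, so the
    pooled t-test is mildly anticonservative; see the methods note.
    """
    rows = []
    if not len(norm):
        return pd.DataFrame(columns=COMPARISON_COLUMNS)
    usable = norm[~norm["censored"].astype(bool)]

    def one(label: str, col: str, lo, hi):
        mats = {}
        for level, g in usable.groupby(col):
            mats[level] = g.pivot_table(
                index=["kit", "sample_id"], columns="assay_id",
                values="norm_cq", aggfunc="mean", sort=True,
            )
        if lo not in mats or hi not in mats:
            return

        def add_row(assay_label, pm):
            tt = stats.paired_t_test(pm.values[:, 0], pm.values[:, 1])
            try:
                icc = stats.icc_twoway_mixed(pm, "consistency")
                icc_val, icc_p = icc.icc, icc.p_value
            except ZeroVarianceError:
                icc_val = icc_p = float("nan")
            rows.append(
                {"comparison": label, "assay_id": assay_label, "t": tt.t,
                 "df": tt.df, "p_two_tailed": tt.p_two_tailed,
                 "mean_diff": tt.mean_diff, "icc_consistency": icc_val,
                 "icc_p": icc_p, "n_pairs": tt.n}
            )

        try:
            add_row("pooled", stats.build_paired_matrix(
                mats[lo], mats[hi], exclude_censored=False))
        except InsufficientDataError:
            return
        for assay in sorted(set(mats[lo].columns) & set(mats[hi].columns)):
            try:
                add_row(assay, stats.build_paired_matrix(
                    mats[lo][[assay]], mats[hi][[assay]],
                    exclude_censored=False))
            except InsufficientDataError:
                continue

    if usable["time_point"].nunique(dropna=True) >= 2:
        tps = sorted(usable["time_point"].dropna().unique())
        one("timepoints", "time_point", tps[0], tps[1])
    if usable["specimen"].nunique(dropna=True) >= 2:
        one("plasma_vs_serum", "specimen", "plasma", "serum")
    return pd.DataFrame(rows, columns=COMPARISON_COLUMNS)


def _well_tally(
    wells: pd.DataFrame,
    censored: pd.DataFrame,
    mask_log: pd.DataFrame,
    excluded_pairs: set[tuple[str, str]],
    cfg: RunConfig,
) -> dict[str, int]:
    """Classify every input well into exactly one accounting bucket."""
    excl = np.array(
        [(a, s) in excluded_pairs
         for a, s in zip(wells["assay_id"], wells["system"])]
    )
    undet = wells["cq"].isna().to_numpy() & ~excl

    # censored-to-floor aggregates and spike-masked tubes
    floor_keys: set[tuple] = set()
    agg_keys = [k for k in io_qpcr.AGGREGATE_KEYS if k in censored.columns
                and k != "dilution_step"]
    flo = censored[censored["censored"].astype(bool)]
    for row in flo[agg_keys].itertuples(index=False):
        floor_keys.add(tuple(row))
    masked_tubes = (
        {tuple(r) for r in mask_log[
            [c for c in normalize.SAMPLE_KEYS if c in mask_log.columns]
        ].itertuples(index=False)}
        if len(mask_log) else set()
    )
    tube_cols = [c for c in normalize.SAMPLE_KEYS if c in wells.columns]

    pair_inc = np.zeros(len(wells), dtype=bool)
    bio = wells["sample_role"].isin(["plasma", "serum"]).to_numpy()
    for i, row in enumerate(wells.itertuples(index=False)):
        if excl[i] or undet[i] or not bio[i]:
            continue
        key = tuple(getattr(row, k) for k in agg_keys)
        tube = tuple(getattr(row, c) for c in tube_cols)
        if key in floor_keys or tube in masked_tubes:
            pair_inc[i] = True

    used = ~(excl | undet | pair_inc)
    tally = {
        "used": int(used.sum()),
        "undetermined_omitted": int(undet.sum()),
        "assay_excluded": int(excl.sum()),
        "pair_incomplete": int(pair_inc.sum()),
    }
    assert sum(tally.values()) == len(wells)
    return tally


def _write_bundle(result: PipelineResult, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "recovery.csv": result.recovery,
        "curves.csv": result.curve_fits,
        "qc_report.csv": result.qc_report,
        "excluded.csv": result.excluded,
        "norm.csv": result.normalized,
        "icc_pairwise.csv": result.icc_pairwise,
        "replicates_icc.csv": result.replicates_icc,
        "scores.csv": result.scores,
        "paired_tests.csv": result.paired_tests,
    }
    for name, frame in tables.items():
        frame.to_csv(out / name, index=False)
    (out / "run_log.txt").write_text("\n".join(result.log) + "\n")
    if cfg.plots:
        _write_plots(result, out)
    manifest = {
        "status": result.status,
        "tally": result.tally,
        "anchor": result.anchor,
        "config": _config_dict(cfg),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _write_plots(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(result.recovery):
        fig, ax = plt.subplots(figsize=(6, 4))
        piv = result.recovery.pivot_table(
            index="kit", columns=["system", "spike_assay"],
            values="median_cq",
        )
        piv.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("median spike-in Cq")
        ax.set_title("Spike-in recovery per extraction kit")
        fig.tight_layout()
        fig.savefig(out / "recovery.png", dpi=120)
        plt.close(fig)
    if len(result.icc_pairwise):
        fig, axes = plt.subplots(
            1, 2, figsize=(8, 4), sharey=True, squeeze=False
        )
        for ax, (phase, grp) in zip(
            axes[0], result.icc_pairwise.groupby("phase")
        ):
            ax.hist(grp["icc"].dropna(), bins=10, range=(0, 1))
            ax.set_title(f"pairwise kit ICC ({phase})")
            ax.set_xlabel("ICC")
        fig.tight_layout()
        fig.savefig(out / "icc_pairwise.png", dpi=120)
        plt.close(fig)


def _config_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    return d
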