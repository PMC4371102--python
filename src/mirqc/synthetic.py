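"""Synthetic study generator with exported ground truth.

Emits complete well tables with the structure the analysis assumes —
several extraction kits, two spike-in controls, endogenous assays,
standard and titration dilution series, RT and qPCR replicates,
no-template controls — from an additive Gaussian model on the Cq
(log2) scale:

    cq = assay_base + system_shift + kit_offset
         + sample_extraction_effect + rt_effect + well_noise

The spike-in assays receive the *same* kit offset, per-tube extraction
effect and RT effect as the endogenous assays of that tube (this is
exactly the mechanism by which spike-in normalisation cancels
extraction bias), but not the endogenous abundance.  Wells whose
latent Cq exceeds the cycle ceiling come out either determined at the
ceiling (within ``undetermined_margin`` cycles above it) or as
undetermined, exercising both censoring paths.

Every latent draw is recorded in a :class:`GroundTruth`, from which
:func:`expected_statistics` computes closed-form expectations (ICCs
from variance components, detection probabilities, accuracy
penalties) for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .metrics import StandardDesign

DEFAULT_ASSAYS = (
    "miR-16", "miR-21", "miR-24", "miR-122", "miR-223", "miR-451",
    "miR-141", "miR-135a*", "let-7a", "miR-26a", "miR-19b", "miR-92a",
    "miR-150", "miR-103",
)
SPIKE_ASSAYS = ("cel-miR-39", "cel-miR-54")


@dataclass(frozen=True)
class KitSpec:
    name: str
    recovery_offset: float = 0.0  # Cq added to everything this kit extracts


@dataclass(frozen=True)
class SystemSpec:
    name: str
    sensitivity_shift: float = 0.0  # Cq added to every well of the system
    noise_sd: float = 0.2  # per-well qPCR noise, Cq
    dye_chemistry: bool = False  # melt flags emitted when True
    melt_fail_rate: float = 0.0  # per-well probability of melt failure


@dataclass(frozen=True)
class TitrationSpec:
    """Pooled cell-line RNA series: concentrated input diluted towards
    the assay's detection limit."""

    n_points: int = 6
    fold_per_step: float = 8.0  # 3 cycles per step at 100% efficiency
    start_offset: float = -10.0  # first point this far below assay base


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and variance components of one simulated experiment.

    Defaults mirror the benchmark layout: 10 plasma samples per kit,
    14 endogenous miRNA assays plus the two C. elegans spike-ins, five
    extraction kits (one with visibly poorer recovery), TaqMan-like and
    miScript-like systems, 7-point 10-fold standard curves and 6-point
    titration curves, censoring at cycle 40.
    """

    n_samples: int = 10
    n_assays: int = 14
    assay_names: tuple[str, ...] = DEFAULT_ASSAYS
    spike_assays: tuple[str, ...] = SPIKE_ASSAYS
    spike_base_cq: tuple[float, ...] = (20.0, 21.0)
    assay_base_range: tuple[float, float] = (26.0, 36.0)
    kits: tuple[KitSpec, ...] = (
        KitSpec("Q", 0.0),
        KitSpec("E", 0.5),
        KitSpec("A", 0.3),
        KitSpec("MN", 0.2),
        KitSpec("NB", 3.0),
    )
    systems: tuple[SystemSpec, ...] = (
        SystemSpec("taqman", 0.0, 0.2, dye_chemistry=False),
        SystemSpec("miscript", 2.0, 0.4, dye_chemistry=True),
    )
    sample_bias_sd: float = 1.5  # per (sample, kit, condition) extraction effect
    rt_rep_sd: float = 0.15  # per-RT-replicate shift, shared across assays
    qpcr_rep_sd: float = 0.0  # extra per-well noise on top of system noise
    n_rt_replicates: int = 2
    n_qpcr_replicates: int = 3
    standard: StandardDesign = field(default_factory=StandardDesign)
    standard_start_cq: float = 18.0
    titration: TitrationSpec = field(default_factory=TitrationSpec)
    low_point_bias: float = 0.0  # Cq bias injected at low standard points
    nonlinear_assays: tuple[str, ...] = ()  # curvature injected in dilutions
    melt_fail_assays: tuple[str, ...] = ()  # dye wells of these always fail
    time_points: int = 1
    time_effect: float = 0.0  # Cq shift of the second time point
    specimen_types: tuple[str, ...] = ("plasma",)
    serum_shift: float = 0.0  # Cq added to endogenous serum values
    ntc_contamination: bool = False
    cq_ceiling: float = 40.0
    undetermined_margin: float = 2.0
    preamplified: bool = True
    seed: int | None = None

    def __post_init__(self):
        for sd in (self.sample_bias_sd, self.rt_rep_sd, self.qpcr_rep_sd):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        if self.n_assays > len(self.assay_names):
            raise ConfigurationError(
                f"n_assays={self.n_assays} exceeds the {len(self.assay_names)}"
                " available assay names"
            )
        if len(self.spike_base_cq) != len(self.spike_assays):
            raise ConfigurationError("one base Cq per spike-in is required")
        bad = set(self.specimen_types) - {"plasma", "serum"}
        if bad:
            raise ConfigurationError(f"unknown specimen type(s): {bad}")


@dataclass
class GroundTruth:
    """Every latent effect behind an emitted well table."""

    assay_base: dict[str, float]
    kit_offsets: dict[str, float]
    system_shifts: dict[str, float]
    system_noise: dict[str, float]
    sample_effects: dict[tuple, float]  # (kit, sample, condition) -> Cq
    rt_effects: dict[tuple, float]  # (system, kit, sample, condition, rt)
    sample_bias_sd: float
    rt_rep_sd: float
    well_noise_sd: dict[str, float]  # per system, incl. qpcr_rep_sd
    cq_ceiling: float


def _condition_label(time_point: int, specimen: str) -> str:
    return f"t{time_point}-{specimen}"


def simulate_study(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw one complete study; deterministic given (cfg, seed).

    Returns the long well table (canonical schema of
    :mod:`mirqc.io_qpcr`) and the ground truth behind it.  Condition
    (time point, specimen) is encoded in ``plate_id`` as
    ``{system}-t{tp}-{specimen}``, so each tube's spike-ins live on the
    same plate as its endogenous wells.
    """
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ConfigurationError("a seed is required for simulation")
    rng = np.random.default_rng(seed)

    assays = list(cfg.assay_names[: cfg.n_assays])
    samples = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    conditions = [
        (tp, spec)
        for tp in range(1, cfg.time_points + 1)
        for spec in cfg.specimen_types
    ]

    assay_base = {
        a: float(v)
        for a, v in zip(assays, rng.uniform(*cfg.assay_base_range, len(assays)))
    }
    spike_base = dict(zip(cfg.spike_assays, cfg.spike_base_cq))
    kit_off = {k.name: k.recovery_offset for k in cfg.kits}
    sys_shift = {s.name: s.sensitivity_shift for s in cfg.systems}
    well_sd = {
        s.name: math.hypot(s.noise_sd, cfg.qpcr_rep_sd) for s in cfg.systems
    }

    sample_eff = {
        (k.name, s, _condition_label(tp, spec)): float(
            rng.normal(0.0, cfg.sample_bias_sd)
        )
        for k in cfg.kits
        for s in samples
        for tp, spec in conditions
    }
    rt_eff = {
        (sy.name, k.name, s, _condition_label(tp, spec), rt): float(
            rng.normal(0.0, cfg.rt_rep_sd)
        )
        for sy in cfg.systems
        for k in cfg.kits
        for s in samples
        for tp, spec in conditions
        for rt in range(1, cfg.n_rt_replicates + 1)
    }

    rows: list[dict] = []

    def emit(plate, system_spec, kit, assay, sample, role, latent, rt, q,
             dilution_step=None):
        raw = latent + float(rng.normal(0.0, well_sd[system_spec.name]))
        if raw > cfg.cq_ceiling + cfg.undetermined_margin:
            cq = np.nan
        elif raw > cfg.cq_ceiling:
            cq = cfg.cq_ceiling
        else:
            cq = raw
        melt = pd.NA
        if system_spec.dye_chemistry:
            if assay in cfg.melt_fail_assays and role != "ntc":
                melt = False
            else:
                melt = bool(rng.random() >= system_spec.melt_fail_rate)
        rows.append(
            {
                "plate_id": plate,
                "system": system_spec.name,
                "kit": kit,
                "assay_id": assay,
                "sample_id": sample,
                "sample_role": role,
                "rt_replicate": rt,
                "qpcr_replicate": q,
                "preamplified": cfg.preamplified,
                "cq": cq,
                "dilution_step": dilution_step,
                "melt_pass": melt,
            }
        )

    log2 = math.log2
    for sy in cfg.systems:
        for tp, spec in conditions:
            cond = _condition_label(tp, spec)
            plate = f"{sy.name}-{cond}"
            time_shift = cfg.time_effect if tp > 1 else 0.0
            spec_shift = cfg.serum_shift if spec == "serum" else 0.0
            for k in cfg.kits:
                for s in samples:
                    tube = (
                        kit_off[k.name]
                        + sample_eff[(k.name, s, cond)]
                        + sys_shift[sy.name]
                    )
                    for rt in range(1, cfg.n_rt_replicates + 1):
                        shift = tube + rt_eff[(sy.name, k.name, s, cond, rt)]
                        for q in range(1, cfg.n_qpcr_replicates + 1):
                            for a in assays:
                                emit(plate, sy, k.name, a, s, spec,
                                     assay_base[a] + time_shift + spec_shift
                                     + shift, rt, q)
                            for sp in cfg.spike_assays:
                                emit(plate, sy, k.name, sp, s, "spike_in",
                                     spike_base[sp] + shift, rt, q)

        # dilution series and NTCs are extraction-free (kit label "none")
        plate = f"{sy.name}-dilutions"
        low = set(cfg.standard.low_steps)
        n_std = max(cfg.standard.abundant_steps + cfg.standard.low_steps)
        for a in assays:
            # non-linear amplification is emulated as saturation: the
            # dilution response plateaus after the second step
            curved = a in cfg.nonlinear_assays
            for step in range(1, n_std + 1):
                eff = min(step - 1, 2) if curved else step - 1
                latent = (
                    cfg.standard_start_cq
                    + eff * log2(cfg.standard.fold_per_step)
                    + sys_shift[sy.name]
                    + (cfg.low_point_bias if step in low else 0.0)
                )
                for q in range(1, cfg.n_qpcr_replicates + 1):
                    emit(plate, sy, "none", a, f"std_s{step}",
                         "standard_point", latent, 1, q, dilution_step=step)
            for step in range(1, cfg.titration.n_points + 1):
                eff = min(step - 1, 2) if curved else step - 1
                latent = (
                    assay_base[a]
                    + cfg.titration.start_offset
                    + eff * log2(cfg.titration.fold_per_step)
                    + sys_shift[sy.name]
                )
                for q in range(1, cfg.n_qpcr_replicates + 1):
                    emit(plate, sy, "none", a, f"tit_s{step}",
                         "titration_point", latent, 1, q, dilution_step=step)
            for q in range(1, cfg.n_qpcr_replicates + 1):
                if cfg.ntc_contamination:
                    emit(plate, sy, "none", a, "NTC", "ntc", 30.0, 1, q)
                else:
                    rows.append(
                        {
                            "plate_id": plate, "system": sy.name,
                            "kit": "none", "assay_id": a, "sample_id": "NTC",
                            "sample_role": "ntc", "rt_replicate": 1,
                            "qpcr_replicate": q,
                            "preamplified": cfg.preamplified, "cq": np.nan,
                            "dilution_step": None,
                            "melt_pass": True if sy.dye_chemistry else pd.NA,
                        }
                    )

    wells = pd.DataFrame(rows)
    wells["dilution_step"] = wells["dilution_step"].astype("Int64")
    wells["melt_pass"] = wells["melt_pass"].astype("boolean")
    truth = GroundTruth(
        assay_base=assay_base,
        kit_offsets=kit_off,
        system_shifts=sys_shift,
        system_noise={s.name: s.noise_sd for s in cfg.systems},
        sample_effects=sample_eff,
        rt_effects=rt_eff,
        sample_bias_sd=cfg.sample_bias_sd,
        rt_rep_sd=cfg.rt_rep_sd,
        well_noise_sd=well_sd,
        cq_ceiling=cfg.cq_ceiling,
    )
    return wells, truth


def simulate_two_rater(
    n: int, sigma_subject: float, sigma_noise: float, seed: int
) -> np.ndarray:
    """Plain two-rater Gaussian data: subject effect plus independent
    noise per rater; analytic consistency ICC is
    sigma_subject**2 / (sigma_subject**2 + sigma_noise**2)."""
    rng = np.random.default_rng(seed)
    subj = rng.normal(0.0, sigma_subject, size=(n, 1))
    return subj + rng.normal(0.0, sigma_noise, size=(n, 2))


def analytic_icc(sigma_subject_sq: float, sigma_noise_sq: float) -> float:
    return sigma_subject_sq / (sigma_subject_sq + sigma_noise_sq)


def expected_statistics(cfg: SimulationConfig, truth: GroundTruth) -> dict:
    """Closed-form expectations implied by the generating model.

    ICCs use the empirical variance of the realised subject effects
    (the assay bases actually drawn) over the analytic noise variance;
    detection probabilities integrate the Gaussian well model against
    the cycle ceiling (interpolation-range censoring, which can only
    tighten them, is ignored here and noted in the methods note).
    """
    bases = np.array(list(truth.assay_base.values()))
    var_base = float(np.var(bases, ddof=1)) if len(bases) > 1 else 0.0
    n_q = cfg.n_qpcr_replicates
    n_spikes = len(cfg.spike_assays)
    out: dict = {}
    for sy in cfg.systems:
        w2 = truth.well_noise_sd[sy.name] ** 2
        cell_noise = (
            cfg.sample_bias_sd ** 2 + cfg.rt_rep_sd ** 2 + w2 / n_q
        )
        out[f"icc_inter_kit_raw_{sy.name}"] = analytic_icc(var_base, cell_noise)
        out[f"icc_inter_kit_norm_{sy.name}"] = analytic_icc(
            var_base, (w2 / n_q) * (1.0 + 1.0 / n_spikes)
        )
        # detection: P(latent + noise < ceiling), averaged over cells
        probs = []
        from scipy.stats import norm as _norm

        sd_cell = math.sqrt(
            cfg.sample_bias_sd ** 2 + cfg.rt_rep_sd ** 2 + w2
        )
        for k in cfg.kits:
            for b in bases:
                mu = b + truth.kit_offsets[k.name] + truth.system_shifts[sy.name]
                if sd_cell == 0.0:
                    probs.append(1.0 if mu <= cfg.cq_ceiling else 0.0)
                else:
                    probs.append(float(_norm.cdf(cfg.cq_ceiling, mu, sd_cell)))
        out[f"p_detect_plasma_{sy.name}"] = float(np.mean(probs))
    # accuracy: zero unless a low-point bias was injected
    design = cfg.standard
    n_ab = len(design.abundant_steps)
    n_low = len(design.low_steps)
    n_cross = n_ab * n_low
    n_lowlow = n_low * (n_low - 1) // 2
    out["expected_A1"] = 0.0
    out["expected_A2"] = (
        -abs(cfg.low_point_bias) * n_cross / (n_cross + n_lowlow)
        if (n_cross + n_lowlow) else float("nan")
    )
    return out


# ---------------------------------------------------------------------------
# scenario presets mirroring the benchmark experiments
# ---------------------------------------------------------------------------

def scenario_presets() -> dict[str, SimulationConfig]:
    """Named configurations for the four study designs.

    * ``five_kits`` — five extraction kits (one with +3 Cq poorer
      recovery) across two systems; recovery and kit-agreement
      analyses.
    * ``two_systems_sensitivity`` — one kit, a low-noise system versus
      one with doubled well noise and a +4 Cq shift that pushes
      near-limit assays over the ceiling (more undetermined wells).
    * ``timepoints_stable`` — 9 samples x 8 assays at two draws a year
      apart with zero true time effect.
    * ``plasma_vs_serum`` — paired specimens with serum running +2 Cq
      (lower measured miRNA) on endogenous assays only.
    """
    base = SimulationConfig()
    paired = replace(
        base,
        n_samples=9,
        n_assays=8,
        kits=(KitSpec("Q", 0.0),),
        systems=(SystemSpec("taqman", 0.0, 0.5),),
        sample_bias_sd=1.0,
        n_rt_replicates=1,
        n_qpcr_replicates=3,
    )
    return {
        "five_kits": base,
        "two_systems_sensitivity": replace(
            base,
            kits=(KitSpec("Q", 0.0),),
            systems=(
                SystemSpec("taqman", 0.0, 0.2),
                SystemSpec("miscript", 4.0, 0.4, dye_chemistry=True),
            ),
        ),
        "timepoints_stable": replace(paired, time_points=2, time_effect=0.0),
        "plasma_vs_serum": replace(
            paired, specimen_types=("plasma", "serum"), serum_shift=2.0
        ),
    }
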