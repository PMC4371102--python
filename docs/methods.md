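# Methods

## The problem

Circulating microRNAs are quantified from plasma or serum by RT-qPCR
as quantification cycles (Cq): the PCR cycle at which fluorescence
crosses threshold, logarithmic (base ≈ 2) in input amount, lower =
more abundant. Benchmarking extraction kits and qPCR chemistries on a
high-throughput platform requires a reproducible analysis chain:
replicate aggregation, assay-level quality control, detection-limit
censoring, normalisation to exogenous spike-in controls, performance
scoring, and agreement statistics. mirqc implements that chain as a
library with a thin CLI, driven by a synthetic study generator so the
whole analysis is testable without any external data.

## Analysis model, in execution order

**Replicate aggregation.** The mean Cq of the qPCR replicate wells of
one reaction is the analysis unit. Undetermined wells (no threshold
crossing) are omitted from the mean; a reaction whose wells are all
undetermined stays undetermined. RT replicates are never pooled:
RT-level and qPCR-level repeatability are analysed as separate axes
(R1/R2 versus R3). The averaging-before-censoring order is a
deliberate choice; averaging censored values would mix a floor
constant into means.

**Dilution curves.** Standard curves (serial dilution of pooled
synthetic miRNAs) and titration curves (pooled cell-line RNA) are fit
by ordinary least squares of mean Cq on log10 relative input, using
only determined points and requiring at least three. An assay is
linear when R² ≥ 0.9. The interpolation range is the span of the
*observed* Cq of the fitted points — the simplest defensible reading
of "the range over which linearity was demonstrated". Amplification
efficiency 10^(−1/slope) − 1 is reported but never gated on.

**Assay QC.** An assay is excluded on its system when any of: (1) a
standard or titration curve is non-linear (either failing suffices);
(2) more than 50% (strict) of plasma/serum reactions are
undetermined, counted at the aggregate (sample × RT replicate) level;
(3) melt-curve failure, for DNA-binding-dye chemistries. Melt curves
arrive as per-well pass/fail flags; the numeric rule — fail when any
no-template-control well fails, or when more than 20% (configurable)
of sample wells fail — is a stand-in for a judgement originally made
visually from dissociation plots, and should be recalibrated against
local practice. A determined NTC more than 5 cycles below the ceiling
raises a contamination warning but never excludes. Spike-in assays
are exempt from QC: they exist to normalise, not to be measured.

**Censoring.** Linearity is only demonstrated inside the
interpolation range, so a determined aggregate above the range's
high-Cq end, or an undetermined aggregate, is below the detection
limit and assigned the cycle ceiling (default 40, matching the
instrument's cycle count). Values *below* the low-Cq end indicate an
unexpectedly concentrated sample, not non-detection: they pass
through unchanged with a `below_range` flag. The titration curve's
range is preferred (it estimates the limit in a realistic RNA
background); the standard curve is the fallback. Censoring is
idempotent and monotone.

**Spike-in normalisation.** Exogenous C. elegans miRNAs (cel-miR-39,
cel-miR-54) spiked into each tube before extraction absorb the tube's
extraction efficiency. For sample X and assay a:

    normCq(X, a) = cq(X, a) − mean(cq(X, spike-ins)) + anchor

`anchor = "auto"` (default) adds back the grand mean of the
per-sample spike means, keeping results on the Cq scale; `anchor = 0`
gives a pure ΔCq. Only conclusions that depend on differences are
anchor-invariant, and those are the supported ones. A sample with one
determined spike-in falls back to it (flagged); with none it is
masked, never imputed. Values censored to the floor are normalised
like any other value but keep their `censored` flag, and are excluded
from agreement statistics by default — 40 is an assignment, not a
measurement.

**Performance scores** (all oriented so higher = better, z-scored
across systems for display):

* Recovery: per-kit median and CV% (sd/mean with n−1) of raw spike-in
  Cq. Low median = good recovery; low CV = even recovery.
* Reproducibility R1/R2/R3: ICC (two-way mixed, absolute agreement,
  single measures) between RT replicates raw, RT replicates after
  normalisation, and qPCR replicate wells raw.
* Accuracy A1/A2: ddCq = |calculated − measured| Cq difference
  between two standard points, where the calculated difference is
  log2 of the design's dilution ratio (100% efficiency assumption; a
  slope-based variant sits behind a switch). All point pairs are used
  (the formula names arbitrary points; adjacent-only is
  configurable). A1 = −mean(ddCq) over pairs within the abundant
  points (s1–s5 of a 7-point design), A2 over pairs touching a low
  point (s6–s7); 0 is perfect. The negated-mean form is a
  rank-preserving reconstruction — any monotone alternative orders
  systems identically.
* Sensitivity S1/S2: determined fraction of censored plasma cells
  (S1) and titration cells (S2); a cell at the ceiling counts as not
  detected.

**Agreement statistics.** Both single-measure two-way ICCs from the
ANOVA mean squares (MS_R subjects, MS_C raters, MS_E residual):

    ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E)
    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k/n (MS_C − MS_E))

with F = MS_R/MS_E on (n−1, (n−1)(k−1)) df for significance.
Consistency is used where a systematic offset between conditions
(kits, systems, time points) is expected and forgiven; absolute
agreement where the same protocol is repeated. Only subjects with
determined values on both sides enter; incomplete and (by default)
censored cells are dropped and counted. No multiple-testing
correction is applied across pairwise tables, as none is part of the
procedure being implemented. Paired two-tailed t-tests compare time
points and specimen types; see the pooling caveat below.

## Synthetic study generator

Additive Gaussian effects on the Cq (log2) scale — the scale on which
all of the arithmetic above operates:

    cq = assay_base + system_shift + kit_offset
         + sample_extraction_effect + rt_effect + well_noise

Spike-ins receive the same kit offset, per-tube extraction effect and
RT effect as the endogenous wells of that tube (the mechanism that
makes normalisation work) but a fixed base abundance. Latent Cq in
(ceiling, ceiling+2] is emitted determined at the ceiling; beyond
that, undetermined — exercising both censoring paths. All randomness
flows from one seeded generator; identical seeds give byte-identical
tables.

Default conditions (chosen once as a realistic circulating-miRNA
study; units are Cq cycles): 10 samples, 14 endogenous assays with
base Cq uniform on [26, 36] (moderate to near-limit abundance), spike
bases 20/21, five kits with recovery offsets 0/0.5/0.3/0.2/3.0 (one
deliberately poor), per-tube extraction bias sd 1.5, RT-replicate
shift sd 0.15 (shared with spike-ins, hence removable by
normalisation), per-well noise sd 0.2 (TaqMan-like) or 0.4
(miScript-like, plus a +2 to +4 Cq sensitivity shift), 7-point
10-fold standard curve from Cq 18, 6-point 8-fold titration curve
starting 10 cycles below each assay's base, ceiling 40. Non-linear
amplification is emulated as saturation (the dilution response
plateaus after the second step, R² ≈ 0.6). Scenario presets mirror
the four study designs: `five_kits`, `two_systems_sensitivity`,
`timepoints_stable` (9 samples × 8 assays, zero time effect, noise
0.5), `plasma_vs_serum` (+2 Cq serum shift on endogenous assays
only — spike-ins are added at fixed amount, so the shift survives
normalisation).

What the generator does *not* emulate: haemolysis and cellular
contamination, heteroscedastic noise (real near-limit wells are
noisier than abundant ones), efficiency differences between assays,
isomiR cross-detection, plate/position effects, and any non-Gaussian
tail behaviour. Passing tests therefore demonstrate correctness of
the computations and the qualitative mechanisms (bias cancellation,
censoring, score ordering), not performance claims about any real kit
or chemistry.

## Numerical choices and edge cases

* Undetermined is NaN end to end; it becomes the number 40 only at
  the explicit censoring step.
* R² is 1 − SS_res/SS_tot (equal to squared Pearson of fitted vs
  observed for simple OLS); a zero-variance dilution series has
  undefined R² and is non-linear by fiat.
* ICC on a constant matrix is a degeneracy error; MS_E = 0 with
  subject spread gives ICC 1 and p = 0 (F = ∞).
* Paired t-test with zero-variance differences returns p = 0 (or 1
  if the mean difference is also 0) with a `zero_variance` flag.
* z-scores use the n−1 sd; a tied metric across systems has no
  z-score and is flagged, never silently zeroed.
* CV uses the n−1 sd (groups of 8–10); groups smaller than 2 report
  a median but omit the CV.
* Exact cancellation claims (normalisation removing shared offsets)
  hold to float rounding, about 1e−15 per operation; tests assert at
  1e−12.

## Open design points, resolved

* **Averaging vs censoring order**: average first (see above).
* **Curves per kit or pooled**: per (assay, system); dilution series
  are extraction-free, so kit is not a natural stratum. Configurable
  upstream by filtering.
* **t-test pooling**: comparisons across time points and specimens
  are reported both per assay and pooled across all sample × assay
  cells. The pooled test is mildly anticonservative under this data
  model: all endogenous cells of one tube share the tube's spike-in
  measurement noise after normalisation (correlation 1/(1+n_spikes)
  of paired differences within a tube), so pooled p-values near the
  threshold should be read with caution. Per-assay differences are
  independent across individuals and the per-assay tests are valid;
  they are the recommended surface.
* **Censored cells in ICC**: excluded by default, includable by
  flag, because a floor value is an assignment.
* **Single vs average measures**: single-measure ICC forms
  (two-rater design); average-measure is a flag away.

## Problem sizes

Tests and the reproduction script run entirely on simulated studies:
roughly 1–11 k wells per study (up to 2 systems × 5 kits × 10 samples
× 16 assays × 2 RT × 3 qPCR replicates plus dilution series and
NTCs), 20-replicate loops for the stochastic order checks, and
n = 2000 subjects for the analytic ICC recovery. The full suite
completes in well under a minute on one core.
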