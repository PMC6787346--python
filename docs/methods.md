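# Methods

This note documents the models, conventions and numerical choices behind
each analysis arm, what the synthetic generators do and do not emulate, and
the problem sizes used by the test suite and `scripts/acceptance.py`.

## MEMRI activity mapping (`scmlab.memri`)

**Model.** Mn²⁺ uptake through voltage-gated Ca²⁺ channels brightens active
tissue in T1-weighted images, but absolute T1 signal is non-quantitative and
carries scan-to-scan global variation. Each scan is therefore reduced to a
per-scan z-map over a caller-supplied brain mask:
`z_i = (x_i − x̄)/D`, with `x̄` and `D` computed over in-mask voxels only.
Voxels with `z ≥ 1` are counted per ROI of a co-registered integer label
atlas, and per-subject counts are compared between groups with a pooled
-variance two-sample two-tailed t-test. Registration and skull-stripping are
out of scope: volumes, mask and atlas must already share one voxel index
space.

**Conventions (all recorded in the `NormalizationRecord`).**

- *Divisor.* The field's shorthand "divided by the variance (σ)" is
  ambiguous (σ conventionally denotes the SD). Both conventions are
  implemented; the default is the sample SD, which makes the output a
  conventional z-score. Since the count statistic is threshold-relative, the
  variance convention merely rescales the effective threshold by 1/σ.
- *Boundary.* `z` exactly equal to the threshold is **counted** (`z ≥ 1`).
- *Dispersion estimator.* Sample (n−1). At brain-mask voxel counts (10⁴–10⁶)
  the n vs n−1 difference is far below count resolution, but it is pinned so
  the brute-force oracle is exact.
- *Multiple comparisons.* Per-ROI t-tests are reported unadjusted at
  α ≤ 0.05, matching common practice for small ROI panels; a BY-FDR column
  is available behind a flag.

**Normalization coupling and phantom design.** A genuine signal increase
confined to one ROI still enters the whole-brain mean and SD, so global
z-normalization slightly *depresses* z elsewhere: with an effect region
occupying fraction f of the mask and shift δ (in SD units), effect-free
voxels shift by ≈ −fδ. The default phantom therefore keeps the effect ROI at
~1.3 % of the brain mask (7³ voxels of a 32³ phantom, 30³ in-mask), where
this coupling is negligible relative to count noise. At f ≈ 3 % the
effect-free-ROI false-positive rate measurably inflates (~12 % at the
default cohort size) — a property of the normalization itself worth knowing
when interpreting "decreases" in non-target regions.

## Actimetry (`scmlab.actimetry`)

**Phase structure.** Lights on 06:00, lights off 18:00 by default
(configurable via `PhaseConfig`); the reference hour for waking-probability
normalization is 18:00, i.e. the final light-phase hour. "Last 4 days" means
the final 96 complete hours ending at the last complete lights-off boundary,
so each analysis period contains one full dark and one full light phase;
partial leading days are dropped.

**Sleep coding.** A 15-min open-field bin with distance exactly 0 is sleep
(0); any strictly positive distance is wake (1). The rule is exact-zero
based: values below measurement resolution but nonzero still count as wake.
Hour-of-day keys use the bin start (a bin starting 17:45 belongs to hour
17); `sample_index` (1–4) is the bin's ordinal within its clock hour and
`period_index` (1–4) the recording day.

**Waking probability.** `p_wake(g, h)` is the mean over animals of each
animal's fraction of awake bins in clock hour h (16 binary outcomes per
animal-hour: 4 periods × 4 samples), with the between-animal SEM reported.
`relative_p_wake` divides by the reference genotype's probability at the
reference hour, so the control at 18:00 is exactly 1. Hour-wise genotype
contrasts come from a logit-link binomial GEE clustered by animal; hours
that are completely degenerate (a genotype uniformly awake or asleep) fall
back to a two-sided Fisher exact test on the pooled 2×2 table, since the
GEE's information matrix is singular there.

**Group-effect regressions.** `fit_phase_effect` fits marginal GLMs by GEE
with an exchangeable working correlation within animal (the repeated
-measures framework named in this literature leaves the working correlation
unspecified; exchangeable is the natural default for period/sample
replicates). Families: log-link gamma for strictly positive continuous
totals, log-link negative binomial for counts, logit-link binomial for
binary outcomes. The negative-binomial dispersion α (Var = μ + αμ²) is
estimated by method of moments from a Poisson working fit and then fixed;
GEE inference is robust to misspecified α, which affects efficiency only.
Effects are reported on the linear-predictor scale relative to the reference
genotype (normalized to 0), matching how such models are usually displayed.
Age/sex columns enter as covariates when present and are otherwise omitted
with a warning.

*Small-sample inference.* With 10–21 animals, the ordinary robust sandwich
is anticonservative. Standard errors use the Mancl–DeRouen bias-reduced
sandwich and p-values use a t reference with df = (animals − coefficients).
Under null simulations at the default cohort sizes this combination holds
the empirical type-I error at 0.038–0.054 (nominal 0.05) over 1000
replicates for both families.

**Hourly wheel profile.** The twelve 5-min counts per clock hour are summed
per animal and day (4 points/hour/animal over 96 h); genotype profiles
average those points; per-hour tests are unpaired two-tailed t-tests on
per-animal means (averaging days first keeps the t-test's independence
assumption at the animal level).

**BY-FDR.** `adjust_fdr_by` is the Benjamini–Yekutieli step-up via
`statsmodels.stats.multitest`, valid under arbitrary dependence:
`p̃_(i) = min_{j ≥ i} p_(j)·m·c(m)/j` with `c(m)` the m-th harmonic number.

## Patch-clamp metrics (`scmlab.ephys`)

**Event detection.** Inward (negative) events over a stationary baseline
(trace median). Candidates come from a two-threshold hysteresis
segmentation of the 0.5-ms-boxcar-smoothed current: trigger at
−`min_amplitude`, release at half that, so noise ripples during an event's
decay cannot retrigger; within a region, overlapping events are separated by
prominent local minima at the refractory spacing (rise + decay template
times, 10 ms by default). Onsets are localized from the half-amplitude
crossing of the rising limb (steep, hence noise-tolerant) backed off by the
template's closed-form half-rise time; candidates are accepted when the raw
waveform over rise + 2 decay constants — truncated at the next candidate —
correlates with the double-exponential template at r > 0.5. All parameters
are explicit; a practical threshold rule used throughout the tests is 3× the
robust noise SD (median absolute successive difference / (0.6745·√2)).
Detection is near-ceiling for amplitudes ≥ 5× noise SD; events closer
together than the refractory spacing are reported once by design.

**Averaging and kinetics.** Event windows (−5/+40 ms) are aligned on the
rising phase in two passes: a first-pass average anchors a reference, then
each window shifts (±2 ms) to maximize its Pearson correlation with the
reference's rising phase and early decay, and is re-averaged. In the
noiseless limit this pins every event at its steepest rise; per-event slope
maxima were found to jitter by >1 ms at moderate SNR and smear the average's
rise time by ~30 %, which motivated the correlation form. Metrics on the
average: amplitude = dominant extremum (baseline already subtracted); 10–90 %
rise time by linear interpolation on the rising limb; decay τ by
least-squares single-exponential fit **from 80 % of peak** down to 10 % of
peak. Fitting from the peak itself is biased ~+16 % for τ_rise/τ_decay = 1/4
because the rising component has not yet died at the peak; the 80 % start
point recovers the true τ_decay within 5 % on the ideal waveform and is
exact for a pure exponential.

**F–I and firing statistics.** A spike is an upward crossing of 0 mV inside
the step window with a 1-ms refractory (threshold and refractory are
parameters; the defaults suit the stereotyped synthetic spikes and typical
striatal recordings). CV(ISI) = SD/mean of interspike intervals, reported
only with ≥ 3 spikes.

**Passive properties.** From a small current step: R = ΔV_ss/ΔI (MΩ from
mV/pA), τ from a single-exponential fit of the charging phase seeded at the
63 % crossing, C = τ/R (pF). The fit rejects responses that do not settle
within a third of the step.

## Synthetic data (`scmlab.synthetic`)

All generators are pure functions of (spec, seed) — reruns are
bit-identical — and their outputs pass the `io_formats` validators
unmodified.

- **Phantoms**: i.i.d. Gaussian voxel noise (mean 1000, SD 50 arbitrary
  units) + additive ROI-confined group shifts in SD units + a per-scan
  multiplicative global factor U(1 ± 0.10) emulating scan-to-scan intensity
  variation (the z-map is exactly invariant to it). Defaults: 32³ grid, the
  seven basal-ganglia/septal ROIs (Cpu, AcbC, AcbSh, GP, LS, MS, BNST),
  8 subjects/group, +1.5 SD in Cpu of the KO group. Not emulated: spatial
  noise correlation, partial-volume effects, registration error — so
  passing tests show the counting/statistics chain is correct, not that the
  method is robust to registration artifacts.
- **Actimetry**: each 15-min bin is awake with p_wake(genotype, hour)
  (defaults: dark 0.95 everywhere; light 0.55 control vs 0.75 mutant);
  awake distances are log-normal (median 300 cm, σ_log 0.5), sleep bins
  exactly 0. Wheel counts per 5-min bin are gamma-Poisson (negative
  binomial, Var = μ + 0.3μ²) with hour-dependent means (dark 150, light 5
  revolutions). 10 animals/genotype, 5 days (so a full last-4-day window
  exists). Not emulated: bout structure/autocorrelation of real sleep,
  ultradian rhythms, inter-animal frailty — within-animal correlation is
  therefore near zero and GEE efficiency gains are modest by construction.
- **Traces**: Poisson event onsets (5 Hz, 60 s), peak-normalized double
  exponentials (τr 2 ms, τd 8 ms, 20 pA) over Gaussian noise (2 pA) at
  10 kHz; fixed amplitudes by default so recovery tolerances are sharp
  (`amplitude_cv` adds log-normal spread). Current-clamp steps: RC
  subthreshold response (R 100 MΩ, τ 10 ms, baseline −65 mV) with
  stereotyped triangular spikes inserted at designed counts per step, so
  F–I recovery is exact by construction. Passive step: closed-form RC
  charging at −70 mV with optional Gaussian voltage noise.

## Problem sizes used in tests and the acceptance script

MEMRI effect recovery: 20 cohorts of 8 vs 8 phantoms at 32³. Null
calibration: 1000 replicates of 6 vs 6 null phantoms at 16³ with 3 ROIs
(3000 per-ROI tests) — the smaller grid keeps the full-suite runtime near a
minute without changing what is being calibrated. Oracle equivalence: 20
phantoms at 24³ against a literal triple-loop tally. GEE recovery: 50 seeds
(13 vs 8 animals × 4 periods, ×1.5 ratio, α = 0.3); calibration: 1000 null
seeds per family. Waking probability: 20 seeds of the default cohort. sEPSC
grid: amplitude {10, 20, 40} pA × noise {1, 2, 4} pA, 60 s each; the
(10 pA, 4 pA) cell sits below any sane detection threshold (2.5× noise SD)
and is the one permitted recovery failure.

## Known limitations

- The z-map normalization couples ROIs through the global statistics (see
  above); large or multiple effect regions bias effect-free ROIs downward.
- The event detector assumes a stationary baseline; slow drift would need a
  running-baseline variant before the hysteresis stage.
- Events closer than the refractory spacing (10 ms at default kinetics) are
  merged, so reported sEPSC frequency is a slight underestimate at high
  rates (~5 % at 5 Hz).
- GEE small-sample corrections are calibrated for the cohort sizes here
  (≥ 10 clusters); with fewer animals the t reference degrees of freedom
  become very small and power is poor.
- Sleep scoring is behavioral (immobility), not electrophysiological; it
  cannot distinguish quiet wake from sleep.
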