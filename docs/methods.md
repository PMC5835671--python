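# Methods

This note documents the models, estimators, defaults and numerical choices
behind `zeitgeber`, and what the synthetic-data validation does and does
not establish about real recordings.

## Time base and hygiene

Activity is recorded as beam-break counts per minute on a 32-channel
monitor and analyzed on a 30-min grid (the conventional bin width for
locomotor analysis; configurable). Zeitgeber time (ZT) 0 is lights-on; all
bins are half-open `[start, start+width)` and day boundaries sit at ZT0,
not midnight. Hygiene rules, applied before any analysis:

* **First-day exclusion.** Animals need a day to adapt to the recording
  tubes; day 1 is dropped and the day axis shifts.
* **Survival trimming.** A terminal run of ≥ 24 h of all-zero bins — one
  full circadian cycle without a single beam break — scores the animal
  dead at the start of the run. Animals dead before completing the 4-day
  analysis window are excluded. The 24-h run length is a configurable
  parameter (`HygieneConfig.death_run_hours`); sleep-plot inspection in
  the source studies names no numeric criterion, so one full cycle is this
  package's operational definition. Missing bins break a zero run:
  absence of data is not evidence of death.
* **Missing data.** Status-flagged monitor rows become missing bins.
  Analyses that need complete series (correlogram, MESA) linearly
  interpolate isolated missing bins and reject series with > 5% missing.

## Rhythmicity detection

Both detectors operate on the mean-subtracted series (optional linear
detrend by flag). Defaults: circadian search band 18–30 h, analysis window
4 days.

### Correlogram, period and RI

The biased autocorrelation estimator (divisor *n* at every lag) is used,
so for a pure sinusoid of period *P* sampled over total span *T*,
r(k) = (1 − k/T)·cos(2πk/P) — a damped cosine. The confidence line is
2/√n, the usual two-sided 95% band for white noise.

Peak bookkeeping follows the correlogram convention in which lag 0 is
peak #1: the peak near one period is #2 and the peak near two periods
is #3, whose height is the Rhythmicity Index. Operationally:

* The correlogram is lightly smoothed (centered moving average, 2.5 h
  width) for peak *localization* only; a raw noisy correlogram has jitter
  maxima at small lags that would otherwise masquerade as "the second
  peak". The period peak is the dominant strict interior local maximum of
  the smoothed curve inside the band (ties broken toward 24 h); a band
  maximum sitting on the band edge is not a peak (monotone correlograms
  carry none).
* The period is then *refined* by a least-squares fit of the closed-form
  template A·(1 − k/T)·cos(2πk/P) over all lags ≥ band_lo/3, on a 0.02-h
  grid within ±3 h of the located peak. A single peak apex carries ~1 h of
  median location error at realistic count rates (~1.5 counts per 30-min
  bin); pooling the whole correlogram brings this to ~0.25 h, close to the
  Cramér–Rao floor for these series. The fit is exact on noiseless
  sinusoids.
* Significance and RI are read from the *raw* correlogram (parabolic apex
  at the located peaks), so RI keeps its interpretation as a correlation
  height: the closed-form example (24-h cosine, 0.5-h bins, 6 days) gives
  RI = (1 − 96/288) = 0.667 at lag 48 h. RI is invariant to affine
  rescaling of counts. The RI peak index is configurable
  (`ri_peak_index`, default 3, searched in the band scaled by
  `ri_peak_index − 1`).
* In `classify()` the correlogram reach defaults to
  min(2.2 × band_hi, span − 1 bin) ≈ 66 h so the RI peak near 48 h is an
  interior point even for 4-day windows; lags beyond half the span are
  increasingly damped by the biased estimator, which RI inherits by
  construction.

### MESA

Maximum entropy spectral analysis models the series as an all-pole (AR)
process and reads the period from the PSD

power(f) = σ²Δ / |1 − Σⱼ aⱼ e^(−i2πfjΔ)|²

on a 1024-point frequency grid covering periods 4–40 h, with parabolic
interpolation of the band peak (grid quantization ≈ 0.15 h near 26 h; the
in-band maximum must again be an interior local peak). AR order defaults
to n/3 capped at 100 — standard practice for short, noisy locomotor
records; a minimum-AIC mode is available.

Two AR fitters are provided. `burg_ar` is the classical Burg lattice
recursion (guaranteed-stable, the textbook maximum-entropy estimator; it
is the oracle-tested reference, recovering known AR(2) coefficients to
±0.05 at n = 2000). The default is `modcov_ar`, the unconstrained
forward-backward least-squares fit (modified covariance method): for weak
sinusoids in counting noise Burg's lattice constraint inflates
period-localization error (median ~0.6–0.7 h at a true 26-h period under
the default study conditions, vs a ~0.29 h Cramér–Rao sd), while the
forward-backward fit achieves 0.20–0.33 h across 22–26 h. Pole stability
is not guaranteed by the least-squares fit, which is irrelevant for PSD
peak reading and surrogate comparisons.

**Significance** uses shuffle (permutation) surrogates: 200 random
permutations of the bins preserve the count distribution exactly while
destroying all temporal structure; the observed band peak power must
exceed the 95th percentile of the surrogate band peaks. (Phase-randomized
surrogates are unsuitable here: they preserve the amplitude spectrum —
including the very spectral peak under test — and so have no power against
periodicity.)

### Dual-criterion call

An animal is rhythmic iff the AC period peak clears the confidence line
AND the MESA band peak beats its surrogate threshold. The conjunction
keeps the false-positive rate on stationary Poisson series well under the
5% of either test alone (measured ≈ 0–2% over 200 nulls). The reported
period is the autocorrelation one; RI is always reported. Total activity
is the 4-day mean of daily counts.

## Group statistics

Summary rows report percent rhythmic over all animals (two decimals, the
`63.64/33` table convention), activity mean ± SEM over all animals, and
period/RI mean ± SEM over rhythmic animals only; SEM = SD/√k with the
n−1 divisor. Comparisons use Welch's *t* (two groups) or one-way ANOVA
with Tukey HSD (three or more; statsmodels implementation) and an
insert-and-absorb compact letter display; star codes at 0.05/0.01/0.001.
All-identical data short-circuit to "no difference" (F is 0/0 there).

## Actograms, profiles, onsets

Double-plotted actograms put day *d* and day *d+1* on one row (rows =
days − 1), so free-running rhythms read as diagonals; shading follows the
four-tone convention (photophase white, scotophase black, subjective day
dark gray in DD, subjective night light gray in LL). Daily profiles
average each animal over its analysis days and then across animals
(mean ± SEM); interval means operate on animal-level sums over a tiling
of [0, 24) — default quarters — feeding the same ANOVA/Tukey machinery.

Onset/acrophase definitions are this package's own (published actograms
mark them without an algorithm): the profile is smoothed with a centered
circular 3-bin moving average; acrophase is the ZT of the smoothed
maximum; onset is the start of the first run of ≥ 2 bins above the daily
mean preceded by ≥ 2 bins below it, scanning circularly from ZT0. Run
lengths are configurable; a flat profile yields both undefined.
Acrophase is equivariant under circular shifts by construction.

## Expression analysis

ΔCt subtracts the per-sample-replicate mean of the two reference genes
(equivalent to a geometric mean of reference quantities). The linear
quantity 2^−ΔCt is divided by the calibrator sample's replicate-mean
linear quantity, making the calibrator's arithmetic-mean RQ exactly 1
(with a single calibrator replicate this coincides with textbook
2^−ΔΔCt). The calibrator defaults to the earliest-timepoint (ZT0) sample
and is configurable; amplification efficiency is fixed at 2. For
between-group contrasts (RNAi vs control) the treated series must be
normalized with the control's `calibrator_scale` so both sit on one
scale; `knockdown_contrast` then reports per-timepoint Welch *t*, stars,
and efficiency 1 − RQ̄_treated/RQ̄_control.

The cosinor model is fitted with the period fixed at 24 h via the
linearization value = β₁cos(ωt) + β₂sin(ωt) + shift, amplitude =
√(β₁²+β₂²), phase = atan2(−β₂, β₁) in (−π, π], with the convenience
conversion acrophase_ZT = (−phase·24/2π) mod 24. Constant data fit as
amplitude 0 with R² defined as 0; designs collapsing onto fewer than
three distinct cycle phases are rejected. Fits use all replicates, not
replicate means. Per-gene rhythm reports combine the ANOVA across
Zeitgeber times with the cosinor R², plus a leave-one-out "fragile" flag
when dropping any single observation lifts the ANOVA p above α — a guard
against significance carried by one replicate.

## Synthetic generator

The behavioral generator draws counts per native 1-min slot from
Poisson(rate) with

rate(t) = baseline·(1 + rel_amplitude·cos(2π(t − acrophase)/P)),

Poisson because beam breaks are event counts. Defaults are the study
conditions of the recordings the pipeline targets: P = 24 h, acrophase
ZT10 (diurnal, major activity before lights-off), baseline 0.05
counts/min (~72 counts/day, the magnitude of the published group means),
rel_amplitude 0.8, 5 recorded days (1 adaptation + 4 analysis), 30-min
output bins, and an additive masking spike (+1 expected count) confined
to the first minute after each lights-on transition — modelling the
startle response to abrupt illumination, present only on LD days.
rel_amplitude is capped at 1 so the rate is never negative. Per-animal
jitter in period/amplitude is available but off by default (the source
data report no inter-individual parameter spread). Free-running cohorts
(true periods ≠ 24 h) are simulated under DD: free-running periods are
expressed in constant conditions, and a 24-h-periodic masking spike would
both be unphysical there and corrupt the period benchmark.

The expression generator inverts the cosinor model exactly —
E(t) = cos(t/24·2π + phase)·amplitude + shift on a 3-h grid, 3 biological
replicates — and maps to Cts as target = ref_ct − log₂E(t) + ε,
references = ref_ct + ε, with ε ~ N(0, sd) on the Ct (log₂) scale, the
standard qPCR error model; shift > amplitude keeps expression positive.
Because RQ is calibrator-normalized, a generator→fitter round-trip
recovers amplitude and mesor up to the factor E(t_cal) (phase exactly);
validation rescales by the known ground-truth calibrator expression.

**What the synthetic validation shows and does not.** Passing tests
establish the estimators' correctness and calibration under
Poisson-noise, single-component sinusoidal rhythms with stationary
baseline. Real recordings add bimodal waveforms, activity bouts with
within-bout correlation, baseline drift with age, weather/handling
artifacts, and non-Poisson overdispersion; the false-positive calibration
and the ±0.5 h period accuracy measured here do not automatically
transfer to such data. The RI-monotonicity check runs at 0.5 counts/min —
ten times the table-level rate — because at 0.05 counts/min the true RI
at the weak-rhythm end (~0.03) lies below the correlogram noise floor and
no estimator could resolve the ordering there.

## Numerical choices and edge cases

* Parabolic (three-point) interpolation refines every discrete peak apex;
  a non-concave triple falls back to the sample value.
* Ties in band-peak height break toward the lag/period closest to 24 h.
* Zero-variance series raise an explicit undefined-correlogram error;
  all-zero channels are excluded upstream with a logged reason.
* Degenerate surrogate fits (singular least squares) count *against*
  significance (peak recorded as +∞).
* Seeds: a single run seed drives every stochastic stage through
  `numpy.random.SeedSequence` spawning; identical seeds give bit-identical
  outputs end to end, and every output file carries the config hash.
* Problem sizes used by the verification suite: 100 random series for the
  oracle check, 50 seeds per true period for recovery, 200 null series for
  calibration, 500 seeds for cosinor recovery — sizes at which the medians
  and rates reported are stable to well within their acceptance margins.

## Known limitations

* Single-beam monitor semantics only (no multibeam/position data); no
  live acquisition.
* No χ² periodogram or Lomb–Scargle baselines; no sleep-architecture
  metrics.
* The 2^−ΔΔCt quantification assumes perfect doubling; no
  efficiency-corrected (Pfaffl) mode.
* Onset/acrophase definitions are declared substitutes for the
  unpublished algorithms behind figure annotations in the source studies.
* The cosinor period is fixed (24 h default); it estimates phase and
  amplitude, not the free-running period — that is the rhythmicity
  module's job.
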