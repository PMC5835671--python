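# zeitgeber

Circadian analysis of insect locomotor activity and diel gene expression,
built around the workflow used for activity-monitor studies of the small
brown planthopper *Laodelphax striatellus*: beam-break recordings from a
32-channel infrared monitor are turned into rhythmicity calls, free-running
period estimates, double-plotted actograms and group summary tables, and
qPCR Ct tables are turned into 2^−ΔΔCt relative-expression time courses
with fixed-period cosinor fits.

It is intended for chronobiologists analyzing DAM-style recordings of
insects (or any beam-break counts) together with diel qPCR time courses,
and for methodologists who need a seeded synthetic generator with known
ground truth to validate such pipelines.

## What it computes

**Rhythmicity (per animal).** After hygiene (first recording day excluded
as adaptation; animals with a terminal ≥ 24 h run of zero counts scored
dead and excluded if they missed the 4-day analysis window), each series is
mean-subtracted and analyzed two ways:

* *Autocorrelation.* The biased correlogram
  r(k) = Σ(xₜ−x̄)(xₜ₊ₖ−x̄)/Σ(xₜ−x̄)². Counting the lag-0 peak as #1, the
  peak near one period (#2) gives the period τ and is significant above the
  white-noise line 2/√n; the height of the third peak (near 2τ) is the
  **Rhythmicity Index (RI)**, the strength-of-rhythm statistic.
* *MESA.* Maximum entropy spectral analysis: an all-pole AR model (forward-
  backward least squares by default; Burg recursion available) evaluated on
  a dense grid over periods 4–40 h. The circadian band peak is significant
  when it exceeds the 95th percentile of band peaks from shuffled
  surrogates.

An animal is **rhythmic** only if both detectors agree; the reported period
is the autocorrelation one. Groups are summarized as in the field's tables
— Rhythmic (%)/n, total activity per day ± SEM, period ± SEM, RI ± SEM —
and compared by one-way ANOVA with Tukey letters (Welch *t* for two
groups).

**Actograms and profiles.** Double-plotted actogram matrices (day *d*
beside day *d+1*, four-tone photophase/scotophase/subjective shading),
across-animal daily profiles with SEM, ZT-interval means with Tukey
letters, and onset/acrophase calls.

**Expression.** 2^−ΔΔCt relative quantification against β-actin + GAPDH
references and a calibrator sample, and least-squares fits of the
fixed-24-h cosine model

    expression(t) = amplitude · cos(2π·t/24 + phase) + shift

with ANOVA across Zeitgeber times and per-timepoint knockdown contrasts
(efficiency plus */**/*** star codes) for RNAi experiments.

**Synthetic data.** `zeitgeber.synthetic` generates activity series
(Poisson counts on a sinusoidally modulated rate, lights-on masking spike,
optional death censoring) and Ct tables (cosine expression, Gaussian Ct
noise, 3-h sampling, 3 replicates) with every ground-truth parameter
recorded, so the whole pipeline is testable without live recordings.

## Worked example

Simulate a small experiment and analyze its LD cohort:

```
$ zeitgeber simulate --seed 42 --n-animals 8 -o demo
$ zeitgeber analyze demo/monitor_LD.txt --label LD --seed 42 -o out
INFO zeitgeber: analyzed 8 animals (7 rhythmic); outputs in out

$ cat out/summary.csv
group,rhythmic_pct_n,total_activity_per_day,period_h,ri
LD,87.50/8,68.75 ± 1.37,24.01 ± 0.11,0.14 ± 0.01
```

Reading the row: 7 of 8 animals passed both rhythmicity criteria (87.50%);
they moved ~69 beam breaks per day; the mean autocorrelation period of the
rhythmic animals is 24.01 ± 0.11 h (the cohort was simulated at exactly
24 h, entrained); and the mean RI of 0.14 is the typical strength of rhythm
at this count rate. Per-animal calls are in `out/rhythm_calls.json`:

```
{"animal_id": "monitor_LD#01", "rhythmic": true, "period_ac_h": 23.48,
 "period_mesa_h": 23.55, "rhythmicity_index": 0.16,
 "total_activity_per_day": 75.5, ...}
```

`out/interval_means.csv` carries the ZT-interval comparison — the ZT6–12
block, where this diurnal species concentrates its activity before
lights-off, takes a distinct Tukey letter:

```
interval,mean,sem,letter
ZT0-6,15.06,0.87,a
ZT6-12,27.88,0.94,b
ZT12-18,20.03,0.63,c
ZT18-24,5.78,0.37,d
```

Expression analysis works the same way from Ct CSVs
(`zeitgeber expression demo/ct_cry2.csv -o out_expr`), reporting RQ per
replicate, the cosinor fit (amplitude, phase/acrophase, mesor, R²) and the
ANOVA-across-times rhythmicity verdict per gene.

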