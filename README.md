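# hforate

Preictal-state identification from intracranial EEG high-frequency
oscillation (HFO) rates.

HFOs — brief (< 100 ms) oscillations in the 80–500 Hz band of intracranial
EEG — are an established biomarker of epileptogenic tissue.  This package
implements, as a tested and reusable pipeline, the analysis needed to ask a
sharper question: does the *rate* of HFOs carry information about an
impending seizure, patient by patient?  It is aimed at researchers in
clinical neurophysiology and seizure prediction who want a reproducible,
end-to-end reference implementation that can be exercised entirely on
synthetic data.

## The method

For each patient with channels grouped into seizure-onset zone (SOZ) and
outside (OUT):

1. **Causal HFO detection.** A Staba-style RMS detector (80–500 Hz
   band-pass, 3-ms RMS, threshold = background mean + 5 SD, ≥ 6 ms, ≥ 6
   rectified peaks above 3 SD) run *pseudo-prospectively*: events are
   emitted in 30-s increments and the background statistics for each
   increment use only the previous 10 min, so detection at time *t* never
   sees data beyond *t*.
2. **Continuous HFO rate.** cHFO(t) = events/min/channel in the minute
   ending at *t*, on a 1-s grid, per channel group.
3. **Rate features.** Over 30-, 15-, and 10-min feature windows: mean,
   variance, OLS slope, quartiles Q1/Q2/Q3, skewness, kurtosis — per group,
   16 features (MEAN-SOZ … KURT-OUT).
4. **Labeling.** Preictal = the one window per seizure ending 1–2 min
   before onset; interictal = non-overlapping windows from 11 min after a
   seizure to 31 min before the next; everything else excluded, with every
   exclusion logged.
5. **Classification.** LASSO logistic regression (penalty chosen by k-fold
   cross-validated deviance, k = training seizure count) on a stratified
   random 2/3–1/3 split, repeated 10× per window length.  All-zero models
   count as non-converged: test AUC 0.5, p = 1.
6. **Significance.** Held-out AUC (Mann–Whitney), label-permutation p-value
   (n = 1,000, plus-one estimator), harmonic-mean combination over the 10
   repeats.  A window "responds" when mean AUC ≥ 0.6 and p < 0.05; a
   responder patient responds in ≥ 1 window length.

A synthetic-data module simulates seizure schedules, per-channel HFO
streams as inhomogeneous Poisson processes (thinning) with configurable
preictal rate ramps and circadian baseline modulation, and raw iEEG with
known oscillatory bursts embedded in 1/f noise — so every stage is testable
against ground truth.  See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

`examples/04_patient_end_to_end.py` simulates one patient (26 h, 12
seizures, SOZ rate ramping linearly to 3× baseline over the last 30 min
before each onset) and runs the full analysis:

```
$ python examples/04_patient_end_to_end.py
30-min window: 12 preictal / 27 interictal observations
15-min window: 12 preictal / 64 interictal observations
10-min window: 12 preictal / 97 interictal observations
 window_len_min  mean_auc     hm_p  n_repeats  n_converged  responder stars
             30       1.0 0.002498         10           10       True    **
             15       1.0 0.001052         10           10       True    **
             10       1.0 0.000999         10           10       True   ***
patient is a responder: True
```

Reading this: each window length kept exactly one preictal observation per
seizure (12) plus the non-overlapping interictal tiling; all 10
cross-validation repeats converged; held-out discrimination is essentially
perfect (mean AUC ≈ 1 against the 0.6 threshold) and the harmonic-mean
permutation p-values are far below 0.05, so the simulated patient is a
responder in all three windows — as it should be, given the strong
simulated ramp.  The other examples show the individual stages: event
simulation (`01`), detection against embedded ground truth (`02`), rates
and features (`03`), and cohort-level feature importance plus the
responder-proportion confidence interval (`05`).

A thin CLI wraps the same library for shell use:

```sh
hforate simulate --seed 1 --out run/        # schedule + events + channels
hforate detect --signal rec.bin --channels run/channels.csv --out ev.csv
hforate run-all --seed 1 --out run/         # full synthetic study
```

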