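# Methods

`hforate` implements a complete analysis chain for asking whether the rate
of high-frequency oscillations (HFOs) in intracranial EEG distinguishes the
half hour before a seizure from ordinary interictal time, patient by
patient.  This note documents the models, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical choices that affect results.

## The analysis chain

1. **Causal HFO detection** (`hforate.detect`).  Channels are re-referenced
   by common average within each electrode type, band-passed to 80–500 Hz
   with a zero-phase Kaiser-window FIR, and reduced to a 3-ms moving RMS
   trace.  A candidate event is a maximal run where the RMS exceeds the
   background mean by `threshold_sd` (default 5) background standard
   deviations; it is kept if it lasts ≥ 6 ms and the rectified signal shows
   ≥ 6 peaks above mean + 3 SD; candidates closer than 10 ms are merged.
   These are the canonical RMS-detector settings and all are exposed in
   `DetectorConfig`.  To emulate real-time operation the detector emits
   events in 30-s increments, computing the background statistics from the
   previous 10 min only; consequently no event ever starts in the first
   10 min of a file, and truncating the future never changes already-emitted
   events (a tested invariant).  A basic artifact stage removes events
   overlapping sharp transients (sample-to-sample steps beyond 8 robust SDs
   of the first difference) or amplitude-saturation plateaus.  This stage
   is intentionally simple; it does not attempt the full artifact/EMG
   batteries of clinical detectors, which is the main fidelity gap of the
   package.

2. **Continuous HFO rate** (`hforate.rates`).  The cHFO rate is the event
   count per minute per channel in a 1-min window slid forward in 1-s
   steps, aggregated separately over seizure-onset-zone (SOZ) and OUT
   channels (resected-volume-only channels are excluded).  Events are
   attributed to windows by their start time; windows are half-open.  The
   rate times the group channel count is exactly the integer window count
   (tested to machine precision).

3. **Rate features**.  Over feature windows of 30, 15, and 10 min
   (advancing on a 1-min grid), eight statistics are computed per channel
   group: mean, variance, OLS slope (rate units per *minute*), the three
   quartiles (linear interpolation), skewness, and excess kurtosis — 16
   features in total.  Variance and higher moments are population moments
   (no bias correction); skewness/kurtosis on a zero-variance window are
   defined as 0 so the classifier never sees non-finite inputs.  These
   conventions are fixed here because they are not standardized elsewhere.

4. **Labeling and exclusion** (`hforate.labeling`).  The preictal period is
   the 31 min before clinician-marked onset: 30 physiological minutes plus
   a 1-min buffer for onset-time uncertainty.  Per seizure and window
   length, the single latest window ending ≥ 1 min before onset is the one
   preictal observation; everything else inside the 31-min zone is
   discarded.  Interictal observations are non-overlapping windows tiling
   the spans from 11 min after a seizure *offset* (the wording "after a
   seizure" is read as after its end, consistent with the 1-min start/stop
   buffer) to 31 min before the next onset, anchored at each span's start;
   partial trailing windows are dropped.  A preictal window overlapping
   another seizure's peri-ictal envelope is redacted, as is any window
   overlapping a data gap or the detector's 10-min warm-up.  Every
   discarded window is logged with exactly one primary reason (priority:
   warm-up ≻ postictal ≻ buffer ≻ preictal-zone ≻ other-seizure ≻ gap ≻
   off-tiling).

5. **Classification** (`hforate.model`).  Observations are split 2/3
   train : 1/3 test at random (stratified within each class; train count =
   round(2n/3) per class with at least one test observation per class —
   e.g. 3 seizures split 2/1, 7 split 5/2).  An L1-penalized logistic
   model is fitted on training features standardized to zero mean / unit
   SD; the penalty is chosen by k-fold cross-validated deviance with k =
   number of preictal training observations (clipped to [2, class
   minimum]), over a 100-point logarithmic grid running four decades down
   from the smallest all-zero penalty.  Selection is the minimum mean
   deviance (a one-standard-error option exists).  The whole cycle repeats
   10 times per window length — up to 30 models per patient; a window
   length with fewer than 3 preictal observations is skipped, mirroring
   the cohort inclusion criterion (≥ 3 usable seizures, ≥ 24 h of data,
   every usable seizure preceded by non-zero HFO rate).  A fit whose
   selected model keeps no features is flagged non-converged and assigned
   chance performance (test AUC 0.5, p = 1).  Class imbalance is accepted
   without reweighting.

6. **Evaluation** (`hforate.evaluation`).  Held-out AUC is the
   Mann–Whitney statistic (ties count half).  Each repeat's AUC is tested
   by permuting the *test* labels 1,000 times preserving class counts
   (models are not refitted per permutation; refitting 1,000 × 30 times
   would be disproportionate and the permutation targets the test
   evaluation), with the plus-one estimator p = (1 + #{AUC* ≥ AUC}) /
   (n+1).  The 10 p-values per window are combined by their harmonic
   mean, with no multiplicity correction by default (a Bonferroni option
   exists).  A window *responds* when mean AUC ≥ 0.6 and combined
   p < 0.05; a patient is a responder with ≥ 1 responding window.  The
   responder-proportion confidence interval is the normal-approximation
   (Wald) binomial interval reported in whole percent, clipped to
   [0, 100] — for 10 of 27 it is 19–55% (Wilson/exact methods are
   selectable; the exact interval is 19–58%).

## Synthetic data: what it emulates, what it does not

`hforate.synthetic` generates (a) seizure schedules by uniform random
packing with a minimum inter-onset gap (default 2 h) and 60–120-s seizure
durations; (b) per-channel HFO streams as inhomogeneous Poisson processes
sampled by thinning; (c) optional raw iEEG: 1/f (pink) Gaussian noise per
channel with Hann-windowed 140-Hz, 50-ms bursts at each event, amplitude =
snr × the channel's 80–500-Hz background RMS, at 4,096 Hz by default.

Baseline rates default to 1.5 (SOZ) and 0.5 (OUT) events/min/channel —
the clinical cohort scale — with 8 SOZ and 40 OUT channels as a typical
implant.  The preictal effect is a multiplicative intensity factor (none /
linear ramp / step) over a configurable horizon; the ramp's magnitude is a
free parameter because no canonical per-patient effect size exists.  OUT
channels can carry their own effect.  Intensity during seizures defaults
to baseline (those windows are excluded downstream anyway).  Baselines are
additionally modulated by a patient-phase sinusoid (default amplitude 0.5,
period 24 h) emulating the strong, well-documented sleep/wake dependence
of HFO rates.  This matters for interpretation: without background
nonstationarity a ramp inflates the window *mean* as sharply as the slope
and the "which feature carries the signal" question is degenerate; with
it, the ramp shape (slope) is the robust signature, as in real data.  One
global integer seed drives everything through independent per-channel
sub-streams.

Not emulated: realistic seizure waveforms, spatial correlation between
channels, rate autocorrelation beyond the sinusoid (no true OU dynamics),
medication taper or electrode settling drift, artifact libraries beyond
simple steps/saturation, and spectral diversity of HFOs (every burst is a
pure windowed sinusoid).  Passing tests therefore show that the pipeline's
logic and statistics behave correctly under controlled conditions — not
that the detector or classifier would achieve these numbers on clinical
recordings.

## Numerical choices

* FIR design: Kaiser window sized for 45-dB one-pass stop-band attenuation
  with transition width = half the low band edge; applied forward-backward
  (zero phase), which doubles the attenuation in dB.  The ~0.1-s filter
  memory is negligible against the 600-s causal background lookback.
* Background statistics are the mean/SD of the RMS trace and of the
  rectified signal over the previous 600 s, per channel.  A flat
  background (zero SD) yields no detections, with a warning.
* The L1 logistic path is solved by cyclical coordinate descent on an
  IRLS quadratic approximation (the glmnet algorithm) with warm starts
  down the grid, an unpenalized intercept, IRLS weights floored at 1e-3
  (the gradient is preserved exactly; the floor only damps steps), and
  early path termination once the training deviance is essentially fully
  explained, stagnates, or a standardized coefficient exceeds 8 (odds
  ratios beyond e^8 per SD never win cross-validation).  The solver is
  verified against an independent L1 solver at fixed penalties to ~1e-4.
  It is implemented in-package (numba) because the calibration studies
  need thousands of cross-validated path fits in minutes.
* Ties in penalty selection resolve to the larger penalty (sparser model).
* All intervals are half-open; all serialized times are seconds from file
  start with 6 decimals; every random quantity derives from one master
  seed via `numpy` seed sequences.

## Study problem sizes

The packaged simulation studies (`hforate.studies`) use desk-scale sizes
chosen to estimate each quantity stably on one CPU: null calibration uses
100 patients × 3 windows (300 patient-windows, 6 seizures and ~24.5 h
each, 4 SOZ / 8 OUT channels, 200 permutations); ramp recovery uses 10
patients (12 seizures, magnitude 3, 30-min horizon, 1,000 permutations);
detector fidelity uses 10 seeds × 900-s recordings at 2,048 Hz (the
detection logic is sampling-rate-agnostic above the 2-kHz floor) with ~100
embedded bursts each.  Under these conditions the null responder rate sits
well inside its binomial band around the nominal 5% and recovery is at
ceiling; scaling patients or seizures down degrades power before it
degrades calibration.

## Known limitations

* The artifact redaction stage is a minimal stand-in for clinical artifact
  suites; on real recordings precision would be lower.
* The permutation test conditions on the fitted model (no refitting), so
  its p-values are calibrated for the test-set evaluation, not the full
  fit-plus-test procedure.
* Random (not chronological) train/test splitting means results do not
  establish prospective prediction performance — the same caveat the
  underlying study design carries.
* With ~40–100 observations and 16 correlated features, LASSO selection is
  unstable across repeats; feature-frequency rankings are therefore
  reported over many models, never from single fits.
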