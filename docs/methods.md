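# Methods

`premove` implements an offline pipeline for detecting the *intention* of a
self-initiated upper-limb movement from EEG, before the movement itself
begins.  It combines the two classical pre-movement correlates — the
event-related desynchronization (ERD) of the sensorimotor alpha (7–12 Hz) and
beta (12–30 Hz) rhythms, and the slow (0.1–1 Hz) movement-related cortical
potential (MRCP) — into one windowed feature vector, classifies rest vs
intention with a sparse discriminant, and evaluates the resulting
asynchronous detector with event-based metrics.  Because no suitable public
recordings exist, a synthetic-data generator with planted, known effects is a
first-class part of the package: every quantitative claim the tests make is a
claim about recovering a planted quantity.

## Signal chain

**Montage.** 32 active electrodes of the international 10/10 system on a
fronto-parietal grid (rows AF/F/FC/C/CP/P), sampled at 512 Hz, earlobe
reference.  The montage is represented on an integer grid; small-Laplacian
neighbor sets are the (up to 4) orthogonally adjacent electrodes, edge
channels keep whatever subset exists.  Two fronto-central channels (FC3,
FC1) are excluded by default via a config drop-list — channel-dependent
feature counts adapt automatically.

**Onset detection.** Kinematic/EMG channels are demeaned, rectified and
averaged; movement onset is the upward crossing of 5% of the maximum
amplitude.  Crossings closer than 2 s are merged — protocol movements are
spaced far wider, so true onsets are never merged.

**Epoching and artifact rejection.** 6-s epochs on [-3, 3] s around each
onset; onsets lacking 3 s of preceding rest are discarded.  Per trial, six
measures (band power in delta/theta/alpha/beta, variance, maximum absolute
amplitude — each per channel, averaged over channels) are compared against
their across-trial means; a trial exceeding 2.5x any mean is masked (never
deleted).  The rule is single-pass; the channel-mean aggregation keeps it
montage-agnostic.  It is invariant to trial order and to a global gain.

**Optimal spatial filters (OSF).** A per-channel weight vector w with
sum(w) = 0 extremizes

SNR(w) = (1/L) Σ_i 10 log10( P_Si / P_Ni ),

where P_Si, P_Ni are mean squared amplitudes of the projection w·x over the
[-1, 1] s (signal) and [-3, -1] s (noise) windows of band-filtered training
trials (0.1–1 Hz for MRCP, maximized; 7–30 Hz for ERD, minimized).  The
search is SLSQP with the single linear equality constraint and an analytic
gradient, started from a CAR-for-anchor vector (Cz for MRCP, C3 for ERD);
any constraint-satisfying improvement is accepted, otherwise the start
vector is returned with a warning flag.  Because the objective is
scale-invariant, the converged weights are unit-normalized for presentation
only.  Within cross-validation the filters are fit on training trials and
applied frozen to the held-out trial.

**Features.** Every feature vector describes one half-open 1-s window
[t-1, t), indexed by its right edge:

* ERD block: per selected channel (small-Laplacian, 512 Hz), the Burg AR(16)
  power spectrum evaluated at integer frequencies 7..30 Hz → 24 bins/channel;
  19 channels → 456 features, plus 24 from the OSF-projected channel.  The
  AR estimator is implemented in-house (vectorized over windows) and verified
  against `statsmodels`' Burg routine to 1e-12.
* MRCP block: per selected channel (CAR, decimated to 64 Hz, 0.1–1 Hz
  zero-phase 2nd-order Butterworth), the 64 window samples; 8 channels → 512
  features, plus 64 from the OSF channel.  Total 1056.

Training uses five rest windows (t = -2 .. -1, step 0.25 s) and one
intention window (t = 0) per trial; testing slides 17 windows over [-3, 0]
(t = -2 .. 0, step 0.125 s).  Features are z-scored with statistics from
training windows only; zero-variance features are flagged and mapped to 0.
The slow-band filtering is zero-phase over the whole 6-s trial before
windows are cut — causal at the trial level only, an offline design; an
online implementation would pay the usual performance cost of causal
filters.

**Classifier.** Two-class sparse discriminant analysis via elastic-net
penalized optimal scoring: iterate (a) a LARS lasso path on the
ridge-augmented design, stopped at the last point whose active set is within
the feature budget K (ties resolve by path order), and (b) a score update
from the class-indicator structure; at most 30 iterations, tolerance 1e-6.
K defaults to (number of training trials - 1) so the within-class covariance
stays estimable; ridge gamma defaults to 1e-2 on normalized features (chosen
by fixture behavior).  The decision value is beta·x + intercept with the
intercept centering the class score means symmetrically; higher = intention.

**Evaluation.** Trial-based leave-one-out; all held-out window scores pool
into one event-based ROC.  Each trial contributes a rest event (grid windows
t in [-2, -1]) and an intention event (t in (-1, 0]); the window ending
exactly at t = -1 is assigned to rest because its data lie wholly in the
rest phase and it is a rest exemplar in training (the assignment is
configurable; the alternative reading is equally compatible with the event
definitions).  Sensitivity/specificity per threshold follow from per-trial
interval score maxima, AUC by the trapezoid rule, and the working point is
the threshold with minimal |sensitivity - specificity|.  A correct trial has
a clean rest event and a detected intention event at that threshold; its
anticipation is its first detection time in (-1, 0].  The empirical chance
level repeats the whole procedure with training labels shuffled per fold
(default 10 permutations); spatial filters and normalization are label-free
and reused across permutations.

## The synthetic generator

One session is a sequence of 13-s trials (10 s movement cue + 3 s rest),
with one self-paced onset per trial, uniform in [3.5, 8] s after the cue —
at least 3 s of rest before and 3 s of data after every onset.  Signals, in
microvolts at 512 Hz on the 32-channel montage:

* Background: per-channel independent 1/f-shaped Gaussian noise
  (exponent 1, 7 uV RMS).
* Rhythms: stationary band-limited Gaussian processes spanning alpha
  (7–12 Hz, 14 uV RMS at the map peak) and beta (13–28 Hz, 9 uV RMS),
  projected through a Gaussian scalp map (sigma 0.85 grid units) peaked at
  C3.  A band-filling process rather than a pure 10/20 Hz line: the
  pre-movement ERD% statistic is a *band mean*, and a single spectral line
  fills one of its five 1-Hz bins, structurally capping the measurable band
  statistic far below the planted depth.  Band-limited noise is also the
  physiologically truer model of mu/beta rhythms.
* ERD: a multiplicative envelope sqrt(1 + depth) on the rhythm components
  only (noise untouched), from 1.0 s before each onset until 1 s after, with
  0.25-s cosine transitions.  The planted % power change is therefore exactly
  100·depth (default -50%).  The 1.0-s lead keeps the effect out of the
  [-3, -1] baseline; a longer lead contaminates the baseline and caps the
  measurable ERD% (with a 1.5-s lead at about -43% for a -50% effect).
* MRCP: a slow negative bump (2-s cosine ramp to the peak at the onset,
  1.5-s cosine rebound) through a map peaked at Cz.  The source amplitude is
  scaled by the inverse of the known noise-free attenuation of the
  measurement chain (CAR map-mean subtraction + 0.1–1 Hz bandpass), so the
  planted parameter (default -5 uV) is exactly what the chain ideally
  measures at Cz.  The near-symmetric bump keeps the filtered peak latency
  near t = 0.
* Trial-to-trial variability — what limits single-trial decoding in real
  EEG: a lognormal per-trial rhythm gain (sigma 0.4), ±50% uniform jitter on
  the ERD depth and the MRCP amplitude, and 0.1-s Gaussian jitter on the
  MRCP peak time.  All are constructed to preserve the *trial-averaged*
  planted values.  Without them the 50-trial decoder saturates (AUC 1.0);
  with them it lands in a realistic operating range (AUC ~0.87-0.91, ~60%
  correct trials at 50 trials).  The absolute SNR was calibrated once to
  that range and then frozen.
* Kinematics: one rectified Gaussian burst (~0.5 s) per movement on an
  auxiliary channel, with its leading 5%-of-maximum crossing at the true
  onset by construction (detector recovery within ~15 ms).

What the generator does **not** emulate: volume conduction through a real
head model (scalp maps are Gaussian), ocular/muscular artifacts (only an
optional amplitude-outlier injector for testing the rejection rule),
non-stationary drifts of rhythm frequency, or any dependence between the
two correlates.  Tests passing on this generator therefore demonstrate that
the pipeline recovers what it is designed to recover under its stated noise
model — not clinical-grade performance on human EEG.

## Numerical choices

* Morlet maps use 7 cycles per frequency, capped so the wavelet stays within
  40% of the epoch duration (affects only the lowest ~2 frequencies of the
  1–50 Hz range, where a 7-cycle wavelet would outgrow the epoch).
* Filter and wavelet transients contaminate roughly one wavelet half-width
  at each epoch edge and would otherwise bias the [-3, -1] baseline
  reference; quantitative time-frequency analyses therefore epoch wider than
  the span of interest and crop (here [-5, 5] cropped to [-3, 3]).
  Reflect-padding is *not* a substitute: the pad is correlated with the
  data, which doubles expected noise power exactly at the boundary.
* Bootstrap significance uses percentile intervals, B = 1000 by default,
  per cell, no multiple-comparison correction.  Percentile intervals on
  skewed per-trial power are anticonservative at small n (measured false
  positive fraction ~0.10 at 40–60 trials, ~0.06 at 150 under a stationary
  null); the calibration test runs at 150 trials.
* The event AUC of a truly uninformative decoder sits slightly below 0.5
  (the rest event spans 9 grid windows, the intention event 8; iid
  simulation of the machinery gives ~0.468), and a single 50-trial estimate
  scatters by ~0.06.  The null-level test therefore averages three replicate
  sessions.
* Zero-variance feature columns and constant AR windows are handled
  explicitly (zero spectrum / zeroed features), so degenerate channels never
  abort a run.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  fitting is deterministic given data and configuration.

## Problem sizes

Unit tests run sessions of 10–60 trials; the statistical end-to-end checks
use the 50-trial session size of the study design, 200 trials for
planted-correlate recovery, and 10 label permutations for the chance level.
The full test suite completes in roughly ten minutes on one CPU.

## Known limitations

* Offline, zero-phase design throughout; online operation is out of scope.
* The OSF solver is local; with the CAR-anchor start it reliably improves
  the objective but global optimality is not claimed (the 3-channel grid
  oracle bounds it on toys).
* Group statistics across subjects (ANOVA, post-hocs) are out of scope;
  "subjects" in this package are seeded synthetic replicates.
* EDF/GDF input is import-only and assumes acquisition-side notch filtering;
  the internal epoch container is the working format.
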