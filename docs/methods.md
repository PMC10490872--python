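# Methods

## Signal model and pipeline

The package targets cue-based two-class motor imagery recorded as
continuous multichannel EEG (microvolts) with one marker per trial.  The
processing order is fixed: channel selection → 8–15 Hz band-pass → ICA
artifact rejection → 0.5–2.5 s epoching → CSP log-variance features →
classification.  Every stage is a pure function of its inputs and the
seeds recorded in the run manifest, so a `RunConfig` fully determines all
outputs.

### Band-pass filter

A Butterworth band-pass of order 4, applied forward–backward
(`sosfiltfilt`), covering 8–15 Hz — the band where event-related
desynchronization of the sensorimotor rhythms is strongest.  Zero-phase
application means epochs are not shifted relative to the cue, at the cost
of doubling the effective attenuation order; the tests verify the pass-band
gain at 11 Hz against the designed frequency response and the absence of
group delay by cross-correlation.

### ICA artifact rejection

Fixed-point ICA with the log-cosh negentropy contrast, symmetric
decorrelation and PCA whitening (scikit-learn's FastICA behind the
`fit_ica` surface).  Components are re-ordered by explained sensor
variance and sign-fixed (largest-magnitude mixing entry positive), pinning
a unique representative of the inherent sign/permutation ambiguity; all
downstream logic is invariant to that ambiguity.

Convergence on band-passed EEG deserves a note.  After narrowband
filtering, most background components are only weakly non-Gaussian, so the
independence contrast is nearly flat on a rotation-invariant subspace and
the symmetric fixed-point update has no sharp optimum there.  A strict
tolerance therefore fails on perfectly reasonable data even though the
strongly non-Gaussian components of interest (discriminative sources,
blinks) stabilized within the first iterations.  `fit_ica` consequently
starts at tol = 1e-4 (max 1000 iterations) and, on non-convergence,
restarts with a fresh derived seed while relaxing the tolerance tenfold per
restart, capped at 1e-2, for up to 8 attempts; the tolerance actually
achieved is recorded in the model and the run manifest.  Only if all
attempts fail is an estimation error raised.

Artifact components are flagged by a dual criterion: |excess kurtosis| >
5 (blinks are impulsive, hence strongly super-Gaussian) or absolute
correlation > 0.8 with any frontal channel low-passed below 4 Hz (the
ocular band).  Both thresholds are configuration values; setting them to
(∞, 1) disables flagging.  Removal reconstructs the sensor signal from the
retained mixing columns — a linear projector, hence idempotent.  Note that
when ICA runs after the 8–15 Hz band-pass (the fixed pipeline order), most
blink energy is already filtered out and the flag set is often empty;
ground-truth artifact-removal checks are therefore run on the raw
simulated recording, where the blink component carries its full
low-frequency signature.

### Epoching

Trials are the half-open sample range
`[onset + round(start·fs), onset + round(start·fs) + round((end−start)·fs))`
with the default window (0.5 s, 2.5 s) after the cue — 200 samples at
100 Hz; a (0, 4) window yields the full 400-sample trial.  A window that
leaves the recording raises an error naming the trial rather than
silently shortening it.

### Common spatial patterns

Per-trial covariances are mean-removed and trace-normalized
(`C = XXᵀ/tr(XXᵀ)`), making them invariant to per-trial amplitude, then
averaged per class.  The whitener `P = Σ^{-1/2}Uᵀ` of the composite
covariance maps `C̄a + C̄b` to the identity; the whitened class
covariances share eigenvectors and their eigenvalue spectra pair to one,
which the implementation measures rather than assumes (λ_b is computed
from S_b explicitly).  Filters are the columns of `W = PᵀV` sorted by λ_a
descending with the same largest-entry-positive sign convention as ICA;
the bank keeps m = 3 filters from each end (six features).  Degenerate
inputs fail loudly: single-class epoch sets, classes with fewer than two
trials, and composite covariances whose smallest eigenvalue is below
1e-10 of the largest (the error suggests channel reduction).

Log-variance features use the unbiased (n−1) sample variance and the
natural logarithm; the choice of estimator and base shifts features by a
constant or scale that every classifier in the comparison absorbs.

### Classifier comparison

Six standard binary classifiers run under seeded stratified k-fold
cross-validation (default k = 10; k = n gives leave-one-out).  Fixed
hyperparameters, chosen once:

| algorithm | settings |
|---|---|
| logreg | unpenalized maximum likelihood, lbfgs, tol 1e-8, ≤1000 iterations |
| lda | linear discriminant, SVD solver |
| svm-rbf | box constraint C = 0.057704, kernel scale 1 (gamma = 1) |
| knn | k = 100 (clipped to n_train−1 with a warning), Mahalanobis metric with ridge-regularized pooled covariance (1e-6·tr/d), inverse-distance weights |
| gnb | per-feature Gaussian likelihoods |
| tree | entropy (deviance) splits, ≤15 internal splits |

The SVM box constraint, the neighbor count and the split cap follow the
optimizer-derived reference configuration for this pipeline; the kernel
scale, for which only a search range is conventionally given, is fixed at
1 so that runs are deterministic.  An iteration cap stands in for
regularization when logistic regression meets separable features.

By default CSP (and hence the features) is refit on the training folds of
each split, so no test-trial information enters covariance averaging or
classifier fitting; a "paper mode" (`refit_csp_per_fold=False`, CLI
`--paper-mode`) fits CSP once on all trials, which is common in the
literature but optimistic.  The mode used is recorded in the report
metadata.  Accuracy (percent, mean over folds) is the headline metric;
2×2 confusion counts are kept for diagnostics.

## Synthetic data generator

`simulate_mi_recording` emulates the cued MI paradigm: 4 s trials at
100 Hz separated by 4 s rest, 100 trials per class by default.  Each of
the n_channels latent sources is Laplace white noise band-passed to
8–15 Hz and normalized to unit variance — non-Gaussian, as ICA
identifiability requires.  Two sources are discriminative: during a trial
of "its" class each has its variance scaled by `erd_ratio` (default 4)
while the other stays at baseline.  This step modulation also makes the
discriminative sources Gaussian scale mixtures, i.e. robustly
super-Gaussian, mirroring the bursty nature of real sensorimotor rhythms.
One source carries blink artifacts: half-sine pulses of 0.3 s (spectral
content < 4 Hz), amplitude 8× the neural source scale, at 10 events/min
(a realistic spontaneous blink rate), mixed through a column concentrated
on the frontal (`Fp*`) channels.  Mixing is a seeded standard-normal
matrix with unit-norm columns (full rank with probability 1); broadband
Gaussian sensor noise is added at `snr_db` (default 10 dB) relative to
the mixed neural signal power.

What the generator does *not* emulate: volume-conduction head geometry,
1/f background spectra, non-stationary drifts, muscle artifacts, or
time-resolved ERD envelopes within a trial (the variance step is constant
over the 4 s trial, which is exactly the structure CSP + log-variance can
exploit).  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not expected accuracy
levels on any particular real dataset.

Default separability was chosen once to represent a good BCI subject:
`erd_ratio=4, snr_db=10` puts 10-fold logistic-regression accuracy near
ceiling, and the hard regime used in the README (`erd_ratio=1.5,
snr_db=0`) pulls it down to the high-70s.  Calibration-sensitive checks in
the test suite use the settings stated alongside them (e.g. variance-ratio
recovery over ≥50 trials/class, permutation-null calibration over 20
repetitions at 30 trials/class).

## Numerical choices and conventions

- Class labels are {1, 2} everywhere; readers map file-level codes (e.g.
  ±1) in first-appearance order.  Marker onsets are 0-based sample
  indices; the MAT reader converts from 1-based positions.
- Integer-typed competition signals are scaled by 0.1 µV/unit by default
  (the distribution's stated quantization); the factor is an explicit
  reader argument because file metadata does not carry it.
- Eigendecompositions use symmetric solvers (`eigh`); ties and sign
  ambiguities are broken by the largest-entry-positive convention, making
  CSP and ICA outputs bit-reproducible for fixed seeds.
- The interchange format is plain HDF5 with a `kind` attribute and
  self-describing datasets; round-trips are bit-exact and dimension
  metadata is stored in the header.
- Problem sizes in the test suite (8 channels, 20–100 trials/class,
  10,000-vector brute-force searches, 20 permutation repetitions) were
  chosen so the full suite completes in well under a minute while keeping
  Monte-Carlo bands meaningful.

## Known limitations

- Binary classification only; multi-class CSP variants are out of scope.
- No regularized/shrinkage CSP: accuracy will degrade when trials are few
  relative to channels (the rank check then fails loudly).
- The ICA tolerance ladder accepts loose convergence on hard data; users
  who need strict convergence can pass `tol`/`max_restarts` explicitly
  and handle the estimation error.
- Bayesian hyperparameter optimization is not included; hyperparameters
  are fixed (an optional grid search can be layered on top by the user).
- Readers cover the continuous-recording MAT layout and the package's own
  HDF5 containers; EDF/BDF/GDF and streaming acquisition are out of scope.
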