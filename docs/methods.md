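# Methods

## The detection problem

Relapse in psychotic disorders is annotated at the day level and is rare
relative to stable periods, so the pipeline is framed as personalized
anomaly detection: for each patient, every model component — feature
normalization, the autoencoder, the clustering — is fit only on that
patient's data, and the autoencoder sees only non-relapse days. Relapse is
then expected to surface as deviation in the learned latent space.

## Preprocessing

Raw streams are cleaned in a fixed order. Samples outside physiologic
ranges are removed first (defaults: heart rate 30–220 bpm, RR 250–2000 ms,
linear-acceleration norm 0–160 m/s², angular norm 0–35; all configurable —
the bounds are plausibility limits, not data-derived). Missing runs of at
most 3 h are filled by linear interpolation between the bounding
observations (averaging a forward and a backward linear fill reduces to
exactly this; leading/trailing runs use nearest-value extension); longer
runs are left missing and the spanned interval is excluded from feature
extraction. Outlier removal precedes imputation, so removed samples become
interpolable gaps.

Ectopic beats are repaired on the RR stream: a sample deviating more than
20% (configurable) from the running median of the five preceding repaired
samples is flagged and replaced by interpolation across accepted
neighbours. At the 5 Hz device rate each beat spans several samples, so an
isolated ectopic is usually restored to its beat's exact value; a sample on
a beat boundary can only be recovered to within the local beat-to-beat
difference. A relative threshold has a known failure mode — if the
tachogram level itself approaches the threshold scale, legitimate variation
is flagged and the repair can lock onto a stale level — which constrains
the synthetic generator's noise structure (below) the same way it
constrains real devices' artifact filters.

## Features, profiles, normalization

Twelve features are computed on each non-overlapping, midnight-aligned
5-min interval: mean linear and angular acceleration norms; mean, max, min
heart rate; mean NN, SDNN, RMSSD; LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz)
power of the NN tachogram resampled to a uniform 4 Hz grid (Welch, 120-s
Hann segments, units ms²); and Poincaré SD1/SD2. All dispersion statistics
use the sample (n−1) divisor, and SD1 is defined through the identity
SD1 = RMSSD/√2 with SD2 = √(2·SDNN² − SD1²), so SD1² + SD2² = 2·SDNN² holds
exactly. An interval is valid when every stream has at least 50% of its
expected samples, at least 10 NN values, no overlap with a discarded span,
and a fully finite tachogram for the spectral features.

Valid intervals are stacked into 48 × 12 profiles covering 4 h,
clock-aligned with a default stride of 48 slots (six disjoint windows per
day; a sliding stride is available — the daily score averages whatever
windows exist). A window containing any invalid slot is dropped whole; no
profile-level imputation. A window is a *sleep* window when at least half
of its slot midpoints fall inside a device sleep epoch, ties counting as
sleep. Per-patient feature means and SDs are computed once on the training
rows and frozen; validation and test profiles are z-scored with those
statistics.

## Autoencoder

The profile autoencoder is a single down/up-sampling pair: a 2D convolution
with 64 filters and an 11 × 12 kernel (the kernel spans the full feature
width, making the operation a 1-D valid correlation along time), LeakyReLU
(slope 0.3), a dense map to 15 latent units, and the mirror image — dense,
LeakyReLU, transposed convolution — back to 48 × 12. The loss is the mean
squared reconstruction error; optimization is Adam at learning rate 1e-4
(batch 32, at most 200 epochs by default) with early stopping after 3
epochs without strict validation improvement, restoring the best epoch's
weights. The implementation is plain NumPy with hand-derived gradients; the
convolution and its transpose are exact adjoints sharing two primitives,
and the test suite checks the full gradient against central finite
differences. Training refuses relapse-labelled profiles by assertion.

## Clustering and scoring

Latent vectors of one patient (within the experiment's sleep stratum) are
clustered with k = 2 by k-means (10 restarts) and by a full-covariance
Gaussian mixture. The mixture is fit from both a k-means++ start and 10
random starts, keeping the higher-likelihood solution: EM started from a
k-means split cannot escape it on strongly anisotropic clusters, while
purely random starts collapse in higher dimensions — the two-scheme fit is
robust to both geometries. Cluster indices carry no meaning, so both
possible cluster→relapse orientations are scored on validation day-level
predictions and the one with the higher harmonic mean of PR-AUC and ROC-AUC
is kept (ties, or a single-class validation set, fall back to the
higher-relapse-fraction rule). The better of the two methods is selected
the same way; ties prefer k-means. Clustering is fit on train+validation
latents; test latents are only predicted.

The daily score is the unweighted mean of the day's window labels (hard
labels by default; mixture posteriors with `soft=True`). Days with no
surviving window are excluded from evaluation rather than scored. PR-AUC is
integrated by the trapezoidal rule through every distinct threshold's
operating point, prepending a zero-recall anchor at the first threshold's
precision; the step-function average-precision estimator is available as an
option. ROC-AUC is the usual trapezoidal rank statistic. The positive rate
(relapse days / days) is reported as the uninformative-scorer PR-AUC
baseline. Feature-level group statistics use the two-sample
Kolmogorov–Smirnov test on daily feature means per sleep stratum, with
Benjamini–Hochberg adjustment across the 12 features within each
(patient, stratum) family. Uncertainty is assessed by retraining under
several seeds and bootstrap-resampling test days with replacement (same
count; a single-class resample is redrawn up to 10 times).

## Dataset splitting

Splits are per-patient and per-event: a maximal run of same-label days is
indivisible. Non-relapse events are assigned greedily in chronological
order to the split with the largest *relative* deficit against an 8:1:1
day-count target (absolute deficits would let the large training bucket
starve the test bucket whenever a patient has only a handful of events,
which is the norm at desk-scale cohorts); exact validation/test ties
alternate. Relapse events are assigned to whichever of validation/test has
fewer relapse days, alternating on ties, approximating the 1:1 target. The
training split never contains a relapse day; this is re-asserted at every
stage boundary.

## The synthetic cohort generator

The generator emulates the statistical structure the pipeline consumes,
not raw-sensor realism. Each patient is four `StateParams` sets
(sleep/awake × relapse/non-relapse). Reported group statistics of wearable
studies are "mean ± SD of daily means", so each state has a day-level mean
draw (`mean_nn` ± `nn_day_sd`, similarly for SDNN and acceleration) plus a
within-day process:

- The NN tachogram is a beat-level process: day mean + LF (0.1 Hz) and HF
  (0.25 Hz) sinusoids + a 0.02 Hz VLF oscillation + an Ornstein–Uhlenbeck
  drift (τ = 45 s, tails truncated at 2.5 σ) + per-beat white noise. The
  variance budget is solved so the extracted 5-min SDNN matches the day's
  target: the OU amplitude is inflated by its expected within-window
  variance fraction, the white share is capped at 2% of the mean NN and the
  OU share at 5% (keeping legitimate beat-to-beat steps far below the 20%
  ectopic threshold), and the total oscillatory excursion is shrunk if it
  would reach the 300 ms floor. The beat mean is compensated for the
  duration-weighting bias of time-sampling a tachogram (long beats occupy
  more stream samples), which applies to the fast variance components only.
  Sleep↔wake parameter transitions ramp over 5 min. The 5 Hz RR stream
  reports the beat covering each sample instant (whether real devices
  beat-resample or emit uniformly is unknown; uniform sampling is used and
  documented); HR is 60000/NN.
- Acceleration is generated as a norm process (state day-level mean + 25%
  within-day noise, configurable to zero) carried by a per-second random
  unit direction, so the mean norm equals the configured level by
  construction. The angular stream uses the same recipe with its own
  parameters.
- Day labels follow a two-state Markov chain whose exit probability is
  1/mean event length and whose entry probability is solved for the target
  stationary relapse fraction, giving contiguous geometric-length events.
- Corruption is injected after clean generation: Poisson-count gaps blanked
  simultaneously in all streams (10% of gaps drawn longer than the 3 h
  imputation limit), isolated ectopic beats (RR × 0.6), and out-of-range
  outliers. Clean copies and injection positions stay on the record purely
  as test oracles.

Calibration is verified end-to-end: streaming a corruption-free patient
through the full pipeline, the extracted daily means of mean NN, SDNN and
acceleration norm fall within 2 standard errors of the configured targets
for every state (120-day check in the acceptance suite; measured systematic
bias is below ~1 ms for mean NN and ~4 ms for SDNN).

What the generator does **not** emulate: circadian structure beyond the
sleep/awake dichotomy, activity-HRV coupling, device-specific artifact
spectra, weekday effects, or gradual prodromes (relapse switches at day
boundaries, matching day-level annotation). Passing tests therefore show
that the pipeline recovers planted state-dependent structure under
realistic sampling, missingness and artifacts — not that it would reach any
particular performance on real patients.

## Study conditions and problem sizes

The standard synthetic study cohort is 10 patients × 21 days (~200 days),
alternating two phenotypes: one whose relapse signature is a sleep-HRV
collapse (shorter NN, halved SDNN during sleep; awake nearly unchanged) and
one with a subtle sleep-acceleration increase and identical awake behavior.
Relapse occupies ~30% of days in events of mean length 2 — chosen so that
three-week patients typically contain at least two relapse events and both
validation and test receive both classes; with multi-month records the
published 8:1:1 / 1:1 event splits are reproduced at their natural scale.
Grid runs in the acceptance suite use `max_epochs=50`. With sleep-state
effect sizes, experiment 7 (sleep/sleep) beats the positive-rate baseline
and experiment 8 (awake/awake) in harmonic mean in at least 2 of 3 master
seeds; the cohort is small enough that single-seed metric values carry
substantial sampling noise, which is why the acceptance properties are
majority-of-seeds orderings rather than point targets.

## Numerical and degenerate-input choices

Zero-variance training features raise (they cannot be z-scored); a
validation set with a single class downgrades orientation to the
relapse-fraction rule with a warning; a patient-stratum with fewer than two
fit latents or no test windows is skipped with a warning and excluded from
pooling; empty streams warn and pass through. The harmonic mean is defined
as 0 at (0, 0). Identical-seed runs are bit-reproducible on one platform;
within a batch, BLAS blocking may differ across row positions by a
last-place unit, so equality tests compare per-call outputs, not row
permutations.
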