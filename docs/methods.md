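# Methods

## The estimation model

Each subject contributes one time-normalized gait cycle: a 303-entry
acceleration row (three pelvis-frame axes × 101 points) and a 2121-entry
output row (12 angle + 9 moment waveforms × 101 points).  The estimator
is a principal-component regression:

1. Center the cohort's input and output matrices column-wise (no
   per-column rescaling: columns within each block share units, and the
   relative amplitudes of waveforms are part of the signal; a
   unit-variance option exists for sensitivity analyses).
2. Retain the smallest number of components whose cumulative
   contribution rate (CCR, cumulative eigenvalue fraction) reaches the
   threshold, default 0.90.  The count is capped at `rows − 1` and at
   the matrix rank.  Component signs are fixed deterministically (the
   largest-magnitude loading entry is made positive) so results do not
   depend on the SVD implementation's sign conventions.
3. Regress every retained output score on all retained input scores by
   ordinary least squares with intercept (no regularization).

Prediction chains projection, regression and reconstruction.  Under
leave-one-out cross-validation the entire chain — including the CCR
component selection — is refit per fold by default, because the
selection rule, not any particular component count, is the method.  A
`frozen` mode selects the counts once on the full cohort and reuses
them in every fold, for studying the sensitivity to that choice.

Virtual-IMU misalignment is applied only at prediction time: models are
calibrated on well-aligned (pelvis-frame) data, and a misaligned sensor
is a perturbation of the deployed input, `a_imu = R_y(θ)ᵀ a_pelvis`.
Positive θ tips the sensor's superior axis toward the subject's right;
all reported errors are symmetric in the sign of θ to within a few
percent, so the sign convention does not affect conclusions.

## Error metrics

NRMSE (%) divides the RMSE between estimated and actual 101-point
waveforms by the actual waveform's peak-to-peak range (normalizing by
the estimate's range is available as an option).  Waveforms with zero
range yield undefined records, which are excluded from summaries and
counted.  The NRMSE ratio divides each subject's condition NRMSE by the
same subject's ZERO-condition NRMSE *before* averaging across subjects;
consequently the ZERO-condition ratio is exactly 1 with SD exactly 0.
Summary SDs use the sample (n − 1) denominator.

## The synthetic cohort generator

The generator emulates the statistical situation the estimator assumes:
a cohort (default 278 subjects) whose acceleration and output waveforms
are smooth, periodic, and driven by one shared latent vector, making the
linear estimator correctly specified.  This isolates the effect of
misalignment from model misspecification: estimation error at ZERO
reflects only PCA truncation and noise, and error growth with θ reflects
only the input perturbation.

Construction, per cohort seed:

- **Basis**: sin/cos pairs for harmonics 1–6 on the cycle plus a
  constant column (periodic by construction; the constant carries
  postural offsets).
- **Mean waveforms**: fixed, deterministic shapes — one oscillation per
  cycle medio-laterally, a dominant two-per-cycle oscillation vertically
  (two steps per stride), amplitudes of order 1–3 m/s²; output means use
  per-variable amplitudes at physiological scale (e.g. tens of degrees
  for sagittal hip/knee angles, ~1 N·m/kg for moments).
- **Latent structure**: latent dimension k = 8 with geometrically
  decaying factor variances (ratio 0.6), so CCR-based selection is
  exercised nontrivially.  Loading directions are random, but every
  latent dimension's stacked loading column is rescaled to a common
  norm, so the population spectrum is exactly the declared geometric
  decay rather than a chi-square-perturbed version of it.
- **Frontal-posture factor**: the third latent slot is replaced by a
  structured mode representing between-subject variation in habitual
  frontal-plane pelvic alignment.  Its input loading is the linearized
  frontal rotation of the mean acceleration pattern (−mean-z in the x
  channel, +mean-x in the z channel); its output loading is a constant
  +1°/−1° (per radian, before scale calibration) offset of the
  frontal-plane pelvis and hip angles.  Real cohorts contain this
  coupling (people differ in standing pelvic obliquity, and the hip
  angle is measured relative to the pelvis), and it is the pathway that
  makes sensor misalignment look like a postural difference to the
  estimator — producing the characteristic error pattern in which
  frontal-plane pelvis and hip angles degrade dramatically with θ while
  other variables barely move.  Placing it in the third slot keeps it
  above the 90 %-CCR retention cut.
- **Scale calibration**: each block's loadings are rescaled by one
  global factor so the average per-variable deviation SD is 12 % of the
  mean waveform's peak-to-peak range, matching the 10–15 %
  between-subject variability typical of lower-limb gait waveforms in
  healthy adults.  A single factor per block preserves the spectrum
  shape while individual variables scatter realistically around the
  target.
- **Noise**: i.i.d. Gaussian, SD 0.05 m/s² on accelerations and 3 % of
  each waveform's own range on outputs — a modest residual consistent
  with trial-averaged data.

What the generator does *not* emulate: biomechanical consistency
between accelerations and moments (no forward dynamics), pathological
gait, skin-motion artifact, non-linear population structure, or
asymmetry between left and right sides.  Passing tests therefore
demonstrate the correctness of the pipeline and the geometry of the
misalignment effect, not the absolute error levels attainable on real
motion-capture cohorts (whose NRMSE magnitudes depend on the true, far
richer population structure).

## Marker-level trials

The trial generator drives the four pelvic landmarks (LASIS, RASIS,
LPSIS, RPSIS) from an analytic pelvis pose: constant anterior
progression with sinusoidal lateral sway (1/cycle), vertical excursion
(2/cycle), and sinusoidal pelvic tilt/obliquity/rotation of a few
degrees; markers at 200 Hz, vertical GRF at 1000 Hz with a double-hump
stance profile (two superposed half-sines, peak 1.1 body weight, stance
60 % of the cycle).  True heel-contact times are embedded in the trial
metadata, and a near-exact analytic mid-ASIS pelvis-frame acceleration
is available for validation; the marker-based preprocessing chain
recovers it to well under 5 % RMS on noise-free trials.

## Numerical and procedural choices

- **Zero-lag filtering**: 4th-order Butterworth applied forward and
  backward (`scipy.signal.filtfilt`), i.e. an effective 8th-order
  magnitude response with zero phase; no cutoff-frequency correction.
  Markers at 10 Hz, GRF at 6 Hz, both configurable.
- **Heel contacts**: upward crossings of a 20 N threshold preceded by at
  least 50 ms below it.  Because a zero-lag filter smears the loading
  onset backward in time (biasing filtered-signal crossings ~15 ms
  early at 6 Hz), the pipeline refines each candidate event at the
  nearest raw-force crossing within one refractory window, with
  sub-sample linear interpolation; timing error on synthetic trials is
  ~3 ms.  Threshold and refractory period are configurable.
- **Central differences**: `a[t] = (p[t+1] − 2p[t] + p[t−1])/dt²`, exact
  for quadratic trajectories; endpoint accelerations are replicated from
  the nearest interior sample so series keep their length through
  normalization.
- **Pelvis frame**: x = unit(RASIS−LASIS); z = unit(x × anterior) with
  anterior provisional from mid-PSIS to mid-ASIS; y = z × x.  Degenerate
  (collinear) landmark configurations raise.
- **Cardan angles**: x-y-z sequence, middle angle in [−90°, 90°];
  |cos θ_y| < 1e−8 raises a gimbal-lock error rather than returning an
  arbitrary decomposition.
- **Time normalization**: linear interpolation onto 101 equally spaced
  instants from heel contact to ipsilateral heel contact, endpoints
  included.
- **Trials per subject**: the cohort carries one waveform set per
  subject, treated as a trial average; the marker-trial generator exists
  to validate preprocessing, not to be averaged into the cohort.
- **Problem sizes**: the packaged analyses use the full default cohort
  (278 subjects, five conditions, leave-one-out) for the study-scale
  run and 100 noise-free subjects for parameter recovery; both complete
  in well under a minute each on a single CPU.

## Known limitations

- NRMSE ratios depend strongly on the denominator (the aligned-condition
  error), which in turn depends on generator noise levels; ratio
  magnitudes on synthetic cohorts are qualitative, not calibrated to any
  particular instrument.
- Only frontal-plane misalignment is modeled; sagittal/horizontal
  misalignment, translation offsets, and IMU noise/bias are out of
  scope (gravity injection is available behind an option on the
  misalignment transform for realism studies).
- The preprocessing stage implements only the pelvis segment; distal
  segment frames and inverse dynamics are outside the package's scope,
  with the synthetic generator emitting angle/moment waveforms directly.
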