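# gaitpcr

Estimation of lower-limb joint angle and moment waveforms during walking
from three-axis pelvic accelerations, and quantification of how
frontal-plane misalignment of the sensor inflates the estimation error.

A single inertial sensor worn on the lower back is an attractive way to
monitor gait outside the laboratory, but it cannot measure joint angles
or moments directly.  A population-trained regression can bridge the
gap: compress each subject's gait-cycle acceleration waveforms and their
joint angle/moment waveforms with principal component analysis (PCA),
then learn a linear map between the two score spaces.  A sensor that is
rotated in the pelvic frontal plane — a common attachment error —
distorts the acceleration input and therefore the estimates.  `gaitpcr`
implements the full analysis on synthetic cohorts with a known
low-dimensional population structure, so every stage can be validated
against ground truth.

## Method

For a cohort of *n* subjects, each contributing one gait cycle
time-normalized to 101 points:

- **Input matrix** `X` (*n* × 303): pelvis-frame mid-ASIS accelerations,
  axes x (medio-lateral), y (anterior–posterior), z (superior–inferior),
  101 points each.
- **Output matrix** `Y` (*n* × 2121): 12 angle waveforms (pelvis, hip,
  knee, ankle × sagittal/frontal/horizontal, degrees, 1212 columns)
  followed by 9 joint-moment waveforms (hip, knee, ankle × the same
  planes, N·m/kg, 909 columns).

Both matrices are centered and compressed by PCA, keeping the smallest
number of components whose cumulative contribution rate (CCR) reaches
90 %.  Each retained output score is regressed on all retained input
scores by ordinary least squares.  Prediction for a new subject is

    ŷ = μ_out + L_outᵀ (B · L_in(x − μ_in) + b₀)

Accuracy is assessed by leave-one-out cross-validation.  A virtual IMU
misaligned by θ in the frontal plane sees accelerations
`a_imu = R_y(θ)ᵀ a_pelvis`; the grid θ ∈ {−20°, −10°, 0°, +10°, +20°}
(labels M20, M10, ZERO, P10, P20) is applied to each held-out subject's
input at prediction time.  Errors are reported as NRMSE (RMSE divided by
the actual waveform's peak-to-peak range, %) and as each subject's ratio
of the condition NRMSE to their ZERO-condition NRMSE.

Because the rotation axis is the y-axis itself, the anterior–posterior
acceleration is exactly invariant under every misalignment angle and the
per-sample acceleration norm is preserved; both are enforced by tests.

The synthetic cohort generator links accelerations and outputs through a
shared latent space (smooth periodic Fourier modes, geometrically
decaying factor variances, additive noise) and includes a frontal-
posture factor — between-subject variation in habitual pelvic frontal
alignment — which couples the x/z acceleration channels to the
frontal-plane pelvis and hip angles.  This is the pathway through which
frontal-plane misalignment corrupts specifically those variables.  A
marker-level trial generator (pelvic landmark trajectories at 200 Hz,
vertical ground reaction force at 1000 Hz) exercises the preprocessing
chain: zero-lag Butterworth filtering (10 Hz markers, 6 Hz force),
heel-contact detection, central-difference acceleration of the virtual
mid-ASIS point, pelvis frame construction, Cardan x-y-z angles, and
101-point time normalization.

## Worked example

```python
from gaitpcr import CohortSpec, generate_cohort, run_loocv
from gaitpcr import evaluate_loocv, summarize

cohort = generate_cohort(CohortSpec(n_subjects=100, seed=0))
result = run_loocv(cohort.subjects)          # five conditions, LOOCV
summary = summarize(evaluate_loocv(result))

piv = summary.pivot(index="variable", columns="condition",
                    values="ratio_mean")
print(piv.loc[["pelvis_frontal_angle", "knee_sagittal_angle"],
              ["M20", "M10", "ZERO", "P10", "P20"]].round(2))
```

```
condition               M20    M10  ZERO    P10    P20
variable
pelvis_frontal_angle  27.37  13.94   1.0  13.90  27.40
knee_sagittal_angle    1.07   1.02   1.0   1.01   1.06
```

Reading: a 20° frontal-plane misalignment inflates the frontal-plane
pelvis-angle error roughly 27-fold relative to a well-aligned sensor,
and a 10° misalignment roughly 14-fold, while the sagittal knee angle is
almost unaffected — misalignment masquerades as a postural difference
and corrupts exactly the frontal-plane pelvis/hip estimates.  The effect
is symmetric in the sign of the misalignment.

Or from the shell:

```sh
gaitpcr run --n-subjects 100 --seed 0 --out run_out
```

which writes `angles.csv` (12 variables), `moments.csv` (9 variables),
`records.csv` (per subject × condition × variable) and a `manifest.json`
recording the resolved configuration and per-fold component counts.

## Documentation

See `docs/methods.md` for the model, the synthetic-data design and its
limitations, and the numerical choices.
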