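# Methods

This note documents the models and procedures implemented in `kinemarker`,
the choices made where the design was genuinely open, and what the synthetic
data does and does not establish.

## Data model and units

Recordings are BVH joint trees with per-frame Euler angles.  Units are fixed
throughout: centimetres, degrees, seconds; entropies in nats.  The suit
configuration is 17 joints × 3 rotation channels = 51 angular DoF at 60 Hz,
with 26 tracked segments (joints plus 9 marker end sites — head top, both
hands, both toes, sacrum, sternum, both acromions — giving 78 position DoF).
A strict BVH tree whose end sites sit only in leaf joints cannot exceed the
body's five extremity leaves, so our parser and writer accept a mild dialect
in which any joint block may carry an `End Site` block alongside child
joints; ordinary single-end-site files parse unchanged.

Euler rotation orders are taken verbatim from each joint's `CHANNELS` line
(intrinsic composition); no global convention is assumed.  Channels are
mapped onto anatomical labels (flexion/abduction/rotation; dominant,
non-dominant or midline side — the writing hand is dominant) through a
declarative alias table that can be extended per vendor in the run config.
Angles are unwrapped modulo 360° before differencing; angular velocities use
central differences (one-sided at the ends) with an optional 4th-order
zero-phase Butterworth low-pass.  The trunk-referenced ("hip") frame
subtracts the root position frame-wise; undoing root yaw is available but
off by default, since only a fixed trunk reference is required.

## Stride segmentation

Stride starts are successive maxima of the reference leg's hip-flexion
angle, subject to a 0.5 s minimum spacing and a prominence of 20 % of the
channel range.  This event fires once per gait cycle and needs no
ground-contact information, at the cost of an arbitrary phase offset
relative to heel strike — harmless, because every consumer uses cycles, not
contact events.  The first and last partial cycles are discarded.  Cycle
normalization resamples each stride linearly onto a fixed grid over
[0, 100)% of the cycle.

## Feature families

The 8-m-walk vector has 31 scalars (F1–F9) and the peg-test vector 33
(F10–F18); the per-family counts follow the published feature table.  Points
where the construction required a decision:

- **Workspace entropy (F1, F12)** is the *unweighted* mean of −ln p over
  nonempty voxels, exactly as defined for the occupancy density.  Note this
  quantity is bounded below by ln K (Jensen), reaching ln K at uniform
  occupancy and growing when occupancy is skewed; it is not the Shannon
  entropy Σ p(−ln p).  Natural log; any log10 display is cosmetic.
- **Autocorrelation PCs (F3)** bin each channel's biased autocorrelation
  into 50 bins of 4 % of the mean cycle (two cycles total), run PCA with
  channels as observations, fix each component's sign so its value at bin 0
  is non-negative, and report PC1/PC2 at the bin containing the 100 %-cycle
  lag.  The all-channels-identical case is rank-0; it is defined to return
  explained variance [1, 0, …] with a degeneracy flag.
- **Delay cross-correlation spectra (F4, F14)** use the correlation matrix
  (channels z-scored; correlation, not covariance) of the stacked delayed
  channels — 51 channels × 10 lags spanning one mean cycle for gait, and the
  upper-body set × 100 lags at 0.1 s steps over a 10 s window for the peg
  test.  Eigenvalues are clipped at zero, sorted descending and normalized
  to sum 1, making the spectrum scale- and channel-order-invariant.  They
  are computed from the T × T Gram matrix of the standardized design matrix
  (identical nonzero spectrum, exact zeros appended), with the valid time
  axis subsampled to ≤ 450 points in the peg-test case; correlation
  estimates at this sample size change the reported ranks (1, 5, 30, 300)
  negligibly.  The upper-body channel set is the trunk/head joints plus the
  task arm (21 channels, so the spectrum has 2100 entries and rank 300
  exists); the resting arm and the seated lower body are excluded.
- **Complexity (F6, F11)** integrates the residual-variance curve
  r(k) = 1 − cumulative explained variance over k/n and normalizes by the
  triangle area 1/2, expressed in percent.  Isotropic motion scores ~100 %,
  one-dimensional motion ~0 %, so *more disordered movement scores higher* —
  the direction in which ataxic gait differs from normal gait.  The count of
  PCs needed for 90 % variance is reported alongside.
- **Head-plane area (F9, F18)** projects trunk-referenced head positions
  onto the plane orthogonal to the mean pelvis→head axis and takes the
  convex-hull area (deterministic and resolution-free; an occupancy-grid
  variant was considered and rejected for its edge-length sensitivity).
  Frontal/sideways standard deviations are taken along the walking direction
  projected into that plane and its in-plane normal.
- **F8** is the 3 × 3 grid of Pearson correlations between the dominant
  leg's {hip flexion, hip abduction, knee flexion} velocities and the same
  three non-dominant channels — 9 coefficients.
- **Task-arm channel sets** (F10, F13, F15): shoulder flexion/abduction/
  rotation, elbow flexion and forearm pronation (the elbow's long-axis
  rotation channel) — five channels.  **F17** fits logistic scales to seven
  velocity channels (the five arm channels plus chest and neck flexion) and
  to the wrist speed, eight values.  These memberships are declared, not
  derivable from the published counts alone, and are configurable.
- **Hand pooling**: every peg-test family is computed per hand on that
  hand's recording and averaged over hands, since the published counts admit
  no per-hand split.  A missing hand falls back to the available one with a
  completeness flag.

## Gaussian-process model and nested evaluation

Features are standardized per training fold; the target is centred and
scaled.  The kernel is an isotropic RBF (Matérn-5/2 available) on the
standardized features with length scale ℓ·√d — parametrized in units of the
typical inter-point distance so one grid serves any subset dimensionality —
plus observation noise.  The posterior is computed in closed form via
Cholesky factorization.  ARD-style per-dimension length scales are supported
in `gp_fit_predict` but are not the default: optimizing them inside the
exhaustive subset search would be computationally disproportionate at this
cohort size.

Nested LOSO: the outer loop holds out all rows of one subject.  On the
remaining subjects the inner loop scores every feature-family subset up to
size 4 (255 subsets over 9 families) by inner leave-one-subject-out RMSE at
default hyperparameters (ℓ = 1, noise = 0.2 on the standardized scales).
Inner-LOSO predictions use the exact block leave-one-out identity
`resid_B = (K⁻¹)_BB⁻¹ (K⁻¹y)_B`, so one factorization serves all inner
folds; a test verifies the identity against explicit refitting.  The subset
proposed most often across outer folds wins (ties: lower mean inner RMSE,
then lexicographic).  Per outer fold, the kernel hyperparameters for the
winning subset are then chosen from a small grid (ℓ ∈ {0.5, 1, 2, 4},
noise ∈ {0.005, 0.05, 0.2, 0.5}) by the same inner-LOSO error, and the
held-out rows are predicted.  Aggregate R² and RMSE pool all out-of-fold
predictions; both repeats of a visit are separate rows throughout.

Controls are included in training for cross-sectional score prediction;
longitudinal mode (baseline features predicting the label at a later
horizon, default 9 months) uses patients only.  Rows without a finite target
are dropped (controls contribute no FXN sample).

The learning curve draws up to 1,000 distinct k-subsets of participants per
k (all of them when C(n, k) ≤ 1,000), runs LOSO within each subset with the
pre-selected families and default hyperparameters via the block identity
(feature standardization uses the whole subset — a deliberate simplification
for this descriptive analysis), and reports the mean and SD of the aggregate
RMSE.  At k = n there is exactly one combination and the SD is 0.

## Synthetic cohorts

The generator defines the study conditions: 9 patients with visits at 0,
0.75, 3 and 9 months and 9 controls seen once; per visit, two 8-m-walk
recordings and two peg-test recordings per hand.  Patient baseline severity
is Beta(1.6, 3.2) on [0, 1] (baseline SARA-like mean ≈ 13, range ≈ 4–30)
drifting at 0.007 month⁻¹; controls are fixed at severity 0.

Gait is a per-joint Fourier template (two harmonics; hip flexion ±25°, knee
flexion 0–60°, cycle 1.15 s, arm swing antiphase to the ipsilateral leg)
driven by a shared cycle clock.  Severity acts through six monotone
disturbance channels, each `base + slope·severity`: per-cycle duration
jitter (0.012 + 0.08 s/s fractional), smoothed tremor on every channel
(0.12 + 0.45°, 4 Hz band), trunk/head sway (0.4 + 5.0°, ~1 Hz), joint
amplitude loss (up to 32 %), inter-joint phase decoupling (slow per-channel
phase wander), and walking-speed loss (up to 38 %), with the cycle also
lengthening by up to 25 %.  The peg test moves the task arm through
minimum-jerk reach–place–return cycles (1.9 s at severity 0, up to 2.2×
longer when severe) with severity-widened target scatter; the other arm
rests and the lower body is static.  The tremor magnitude and bandwidth were
chosen so that the movement slowdown, not the tremor's own velocity content,
dominates the arm-speed scales — intention tremor in this disease is small
relative to voluntary movement.  Labels: SARA = 4 + 28·severity + N(0, 1.5)
clipped to [0, 40]; SCAFI = 1.4 − 2.5·severity + N(0, 0.15);
FXN Ct = 5 + 2·severity_trait + N(0, 0.3) with the *baseline* latent, since
frataxin expression does not track short-term clinical change.  Controls
evaluate the same SARA formula at severity 0 (≈ 4 points) rather than the
literal 0 printed for real controls — one generative formula for everyone
was preferred over a special case.  Kinematics and labels draw from
independent random streams, so label noise can be re-drawn without changing
recordings; identical spec + seed reproduce the cohort bit-for-bit.

What the simulator does *not* emulate: biomechanically valid dynamics,
ground reaction, foot-ground contact, sensor drift or soft-tissue artefact,
speech, and any non-monotone or heterogeneous symptom structure.  Passing
tests therefore demonstrate that the pipeline recovers the constructed
severity signal under realistic noise magnitudes — not that it would achieve
the same accuracy on real patients.

## Numerical choices and degenerate inputs

Voxel grids snap their origin to the edge length, making counts invariant
under whole-grid translations.  Autocorrelations use the biased (1/N)
estimator, so lag 0 is exactly 1.  FWHM interpolates the first 0.5 crossing
linearly and saturates (flagged, not raised) at twice the maximum lag.
Kernel matrices get a 1e-8 jitter; duplicated rows are tolerated.
Zero-variance channels are an error wherever a correlation is required, and
rank-0 PCA inputs raise.  Head-plane collinearity returns area 0 with a
degeneracy flag.  Feature extraction failures are recorded per row in the
cohort table rather than aborting the run.

## Problem sizes

The default analyses use the 18-subject cohort (90 subject-visit-repeat
rows), 10 random seeds for pipeline-recovery medians, 5 permutations for the
null, three label-noise levels for the noise sweep, and up to 1,000
combinations per learning-curve point — sizes at which the reported medians
are stable from run to run.

## Known limitations

FXN prediction on the default cohort reaches R² ≈ 0.1–0.3: with nine
patients, a time-invariant molecular target and Ct noise of 0.3 against a
trait signal of SD ≈ 0.4, the achievable ceiling is modest; the analysis is
reported as constructed rather than tuned to look stronger.  The paper-scale
channel bookkeeping of the commercial suit (e.g. a 31-channel upper-body
set) cannot be reproduced exactly with a uniform 3-channels-per-joint
hierarchy; the nearest consistent set (21 channels) is used and documented.
The exhaustive selection operates on feature families, not individual
scalars, which keeps the search space meaningful at 2⁹ rather than 2³¹.
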