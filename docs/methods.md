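# Methods

`aclgait` implements an end-to-end analysis for discriminating
post-ACL-reconstruction from healthy athletes using four lower-limb
inertial sensors (left/right shank and thigh) worn during a
run-and-sidestep task, together with a synthetic-data generator that
stands in for human recordings.  This note documents the models,
parameters and numerical choices, and what the synthetic conditions do
and do not establish.

## Synthetic data generator (`aclgait.synth`)

Each repetition emulates the test protocol: a deep squat (used for
cross-sensor synchronization), a short run of strides, a 45° sidestep to
the left or right, and a deceleration to a stop.  Units are g for
acceleration and deg/s for angular rate, matching the ±16 g / ±2000 deg/s
sensing ranges of the emulated hardware; axes are x = mediolateral,
y = anteroposterior, z = vertical.

**Stride waveform.** The mediolateral shank angular rate is a template,
not a musculoskeletal simulation: one dominant positive Gaussian lobe at
mid-swing (320 deg/s, σ = 45 ms) flanked by negative lobes at initial
contact (−120 deg/s) and terminal contact (−160 deg/s), the morphology
shank gyroscopes show in running and the shape the event detector keys
on.  Thigh sensors carry an attenuated (0.35×) flexion component plus a
leg-swing angular-rate component perpendicular to the flexion axis that
is shared between shank and thigh of the same leg — this shared
component is what makes the hinge-axis estimation well-posed.

**Study conditions.** The per-(cohort, limb) gait-cycle-time and
relative-stance means default to the emulated study's descriptives
(post-ACL left 0.514 s / right 0.503 s; healthy left 0.490 s /
right 0.509 s; stance 44.75 / 44.70 / 43.40 / 45.35 % of GCT).  Cadence
is 1/GCT by definition, so the cohort cadence contrast follows from the
GCT cells.  Stride-to-stride sd (0.085 s) and subject-to-subject sd
(0.030 s) combine to ≈0.09 s, the scale of the reported dispersions.
The affected limb of the post-ACL cohort additionally receives a
roughness multiplier (default 1.5) on band-limited >6 Hz acceleration
noise (base sd 0.03 g), motivated by the association of jerk-like
high-frequency content with instability after ACL reconstruction.  No
amplitude statistics were available for the accelerations, so amplitudes
(impact transients 1.5 g at the shank, gait oscillations 0.15–0.3 g) are
plausible choices for running, not calibrated values.

**Clock and mounting model.** Per sensor and repetition: a constant
clock offset uniform in ±0.5 s, a rate error uniform in ±1%, and 1 ms
Gaussian sample-time jitter; shank sensors are additionally yawed about
the vertical by up to ±15°.  These distortions exist purely to exercise
resampling, squat synchronization and frame alignment; ground truth
(contact times, offsets, yaws) travels with every repetition for oracle
tests.

**What passing tests show.** The generator produces the *temporal* and
*roughness* structure the pipeline is sensitive to, with subject-level
random effects so that leave-one-subject-out evaluation is meaningful.
It does not reproduce kinematic amplitude distributions, soft-tissue
artifacts, fatigue drift, or between-day variability of real athletes;
classification results on it validate the protocol's correctness
(chance level on null data, signal detection at programmed contrasts),
not field performance.

## Preprocessing (`aclgait.preprocess`)

*Resampling* is piecewise-linear onto an arithmetic grid
(`floor(span·rate)+1` samples); at 100 Hz and <20 Hz signal content the
linear-interpolation error is negligible relative to sensor noise, and a
spline is a straightforward substitution if ever needed.

*Squat synchronization* detects the minimum of the 1 Hz-low-passed
vertical acceleration in the leading 5 s window (4th-order zero-phase
Butterworth), refined to sub-sample precision with a three-point
parabola; a valley depth below 0.15 g raises an explicit sync failure.
The left shank is the fixed reference sensor (offset 0) — an arbitrary
but reproducible choice.  With zero clock-rate error the programmed
offsets are recovered to well under one sample; a ±1% rate error adds up
to ≈10 ms of irreducible bias at a squat placed ~1 s into the recording.

*Shank frame alignment* estimates the knee flexion axis `j` in the shank
frame by minimizing `Σ_t (‖ω_shank(t)×j‖ − ‖ω_thigh(t)×x̂‖)²` — for a
hinge joint the angular-rate magnitude perpendicular to the joint axis
must agree between the two segments.  The minimization is damped
Gauss–Newton on the unit sphere, multi-started from the six signed
coordinate axes, iteration cap 200, stopping when the cost improvement
falls below 1e-10 (relative).  Only the yaw (rotation about the
vertical) is corrected, the sign being fixed so mid-swing angular rate
about the new x-axis is positive; whether a full 3-D sensor-to-segment
rotation is preferable was left open by the source procedure and the
vertical-only rotation is this package's documented choice.  A
directional-anisotropy ratio (dominant over second gyro eigenvalue,
threshold 3) flags low-confidence fits — flexion-poor or pure-noise
inputs fail loudly rather than silently mis-rotating.

## Gait events and stride parameters (`aclgait.gait`)

Mid-swing peaks are local maxima of the mediolateral shank angular rate
above 0.6 × the 95th percentile of its positive samples, with a 0.3 s
refractory period; terminal contact is the last negative peak before
each mid-swing and initial contact the first negative peak after it.
Peak times are parabola-refined.  The thresholds are this package's
documented operating point — the cited event-detection literature does
not pin them down.  Per complete IC→IC cycle: GCT, STP, SWP,
rSTP = 100·STP/GCT, rSWP = 100 − rSTP, cadence = 1/GCT.  A validity
filter (configurable) drops strides with GCT outside [0.2, 1.2] s or
rSTP outside [20, 80]%, which removes run-up, braking and sidestep
artifacts; steps during the sidestep that pass the filter are retained.
On noise-free synthetic trains events are recovered within one 100 Hz
sample period (the residual ≈2 ms stance bias comes from overlapping
template lobes shifting the negative peaks).

## Feature registry (`aclgait.features`)

Thirteen scalar signals per sensor feed the descriptive statistics
(3 gyro axes, 3 jerk axes, 3 body- and 3 gravity-frame acceleration
axes, acceleration magnitude).  Gravity is a zero-phase 4th-order
Butterworth low-pass at 0.3 Hz (configurable); the body component is the
exact complement.  Jerk is the central-difference derivative of
acceleration (one-sided at the ends).  Spectral features use a
Hann-windowed, linearly detrended periodogram: dominant frequency
(argmax, DC excluded), power-weighted centroid, 95% spectral edge
frequency, harmonic ratio (even/odd harmonic power over the first 10
multiples of the dominant frequency, nearest-bin lookup) and index of
harmonicity (dominant power over the first 6 harmonics' cumulative
power).  Sample entropy uses m = 2, r = 0.2·sd under the Chebyshev
metric with self-matches excluded, both template lengths ranging over
the first N−m starting points.  SPARC uses a 4-level zero-padded FFT,
10 Hz frequency cutoff and 0.05 adaptive amplitude threshold.  The
dimensionless jerk is −(T³/peak²)·∫(da/dt)²dt with the negative-log
variant exposed as the registry feature; both are amplitude-scale
invariant.

The registry totals 223 features per sensor, 892 per repetition over
four sensors.  The emulated study reports 250 features per repetition
but its appendix listing is not available and the stated families do
not obviously arithmetic to that count, so the registry composition here
is explicit, configurable (including a single-sensor variant) and
schema-tested rather than claimed to match the original.  Undefined
values (zero-variance correlations, spectra of all-zero signals,
CV at zero mean) are NaN and explicitly listed in the vector's `flagged`
set; the design-matrix builder replaces them with zero for model fitting
and reports which columns were affected.

## Group statistics (`aclgait.stats`)

Levene's test is a one-way ANOVA on absolute deviations from the group
mean (median optional, giving Brown–Forsythe).  The condition × limb
ANOVA uses effect (sum-to-zero) coding with Type III sums of squares —
the convention mainstream statistics packages default to for unbalanced
factorial designs — computed per coefficient as β²/[(XᵀX)⁻¹]ⱼⱼ; the
full-model and residual SS are reported so the OLS decomposition is
checkable.  Cohen's d defaults to the equal-weight pooled sd
√((s₁²+s₂²)/2), which reproduces the published left-leg GCT/STP/SWP
effect sizes from the published descriptives; sample-size weighting is
available (the published cadence cell is closer to the weighted
variant).  Power analysis is exact noncentral-t (df = 2n−2,
noncentrality d·√(n/2), two-sided), searched by doubling plus bisection
for the smallest n reaching the target; this reproduces 26 per group at
d = 0.8 and 137 at d = 0.34 (α = 0.05, power 0.8).

## Learning protocol (`aclgait.evaluate`)

Subjects are split 6/2/4 (train/validation/test) with equal cohort
counts in every partition; general cohort sizes are allowed when exactly
proportional.  Hyper-parameter and select-K-best grids (K ≤ 10, scored
by the one-way F statistic; mutual information is a drop-in alternative)
are searched by leave-one-subject-out cross-validation, maximizing mean
per-subject accuracy; ties break towards the smallest K then the
lexicographically first parameter combination, for determinism.
Standardization and feature selection are fitted inside each training
fold only.  The validation step is confirmation-only (it records
generalization but does not overturn the grid optimum).  Training and
validation are then merged (8 subjects), the grid re-tuned via LOSO, and
the final model scores the 4 test subjects; over the random partitions,
per-subject accuracies accumulate (mean and SE = sd/√n over players are
reported) and test confusion counts are pooled.  Mean per-player
accuracy and pooled-matrix accuracy differ slightly by construction;
both are available, labeled.  The positive class is post-ACL throughout.
Documented default grids: kNN k ∈ {1,3,5,7,9}; SVM (RBF) C ∈ {0.1,1,10},
γ ∈ {scale,0.01,0.1}; XGB depth ∈ {2,3,4}, trees ∈ {50,100,200},
learning rate ∈ {0.05,0.1,0.3}; MLP hidden ∈ {(16,),(32,),(32,16)},
L2 ∈ {1e-4,1e-3}; stacking uses the five base families under a
logistic-regression meta-learner.  One master seed expands into
recorded per-permutation seeds.

A structural leakage guard backs the protocol: fitting functions receive
only the rows of the permitted subjects and raise if a forbidden subject
appears; a test verifies the fitted state is byte-identical when the
held-out subjects' rows are deleted from the dataset.

## Problem sizes and acceptance checks

The published headline accuracies cannot be reproduced without the human
recordings, so the pipeline's acceptance checks are property-based, run
at the study's design size (6+6 subjects × 10 repetitions, four sensors,
100 Hz) with a compact kNN grid (k ∈ {3,5}, K ∈ {3,10}) and 2–3
partition permutations — the protocol under test is identical at larger
grids, which only scale runtime.  Three conditions are checked: null
cohorts (identical distributions) must classify inside the binomial 95%
band of 50%; cohorts at the study-scale asymmetry must classify above
chance (one-sided binomial p < 0.05); cohorts with a strongly increased
affected-limb roughness (multiplier 4) must exceed 90% mean per-subject
accuracy.  At the study-scale condition the protocol lands at ≈72% mean
accuracy on the synthetic data — consistent in magnitude with the
emulated study, though that agreement is a property of the chosen
generator contrast, not evidence about real athletes.

## Known limitations

* The stride template is fixed; real shank angular-rate morphology
  varies with speed, footwear and surface, and the event detector's
  thresholds may need retuning on real data.
* Only yaw misalignment of the shank sensors is modelled and corrected;
  pitch/roll mounting errors and soft-tissue wobble are absent.
* The roughness contrast is a single band-limited noise multiplier; real
  post-ACL signatures are richer (kinematic, kinetic and
  neuromuscular-control differences).
* Sample entropy is O(N²) per channel; at the default repetition length
  (~650 samples) this dominates feature-extraction time (~0.8 s per
  repetition, single CPU).
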