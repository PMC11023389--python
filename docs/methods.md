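# Methods

This note records the models, conventions and numerical choices behind the
package, and what its synthetic validation does and does not establish about
real motion-capture data.

## The variance decomposition

The elemental variables are the seven joint angles of the
shoulder–elbow–wrist chain, ordered wrist (q1–q3), elbow (q4), shoulder
(q5–q7), in degrees, as trial ensembles of shape (N_trials × 100 × 7) on a
time base normalised to 0–100 % of the movement. At each time point the
Jacobian of a candidate performance variable with respect to the angles is
estimated by ordinary least squares of the mean-free performance-variable
deviations on the mean-free angle deviations. Both sides are mean-centred,
so the regression has no intercept (it is analytically zero); the solver is
rank-revealing (`numpy.linalg.lstsq`), and a rank-deficient predictor matrix
yields the minimum-norm solution with a warning. At least n + 1 = 8 trials
are required; the study design's 20 trials per condition is the default.

The null space of the Jacobian is computed by SVD
(`scipy.linalg.null_space`) with the standard tolerance
eps · σ_max · max(shape). If the Jacobian itself loses rank, the null-space
basis widens to n − rank columns; the divisor d in the variance equations
stays the nominal dimension of the performance variable and the time point
is flagged in `rank_deficient_`.

Deviations are projected with the orthogonal projector B Bᵀ; the variance
divisors are (n − d)·N and d·N with N the trial count — the plain-N
convention of the defining equations — and `ddof_compat=True` switches to
N − 1 for comparison with packages that use the unbiased divisor. Units
cancel in ΔV, so angles stay in degrees throughout the decomposition.

A time point with zero total variance has no defined ΔV; it is reported as
NaN, and the proportion-above-threshold summary excludes NaN points from
both numerator and denominator rather than counting them as non-synergy.

Group curves average V_UCM and V_ORT across participants at each time point
and compute ΔV from those averages. The alternative (averaging
per-participant ΔV) is deliberately not used: the two orders of operation
differ whenever participants' total variances differ, and the
component-first scheme is the one the group summaries here are defined by.
Raw components are averaged, with no Fisher-style transformation of ΔV.

## Performance variables

Six hand variables come from the forward-kinematic chain: position, velocity
and orientation, each in the internal (shoulder) or external (lab) frame.
Orientation is expressed as intrinsic XYZ Euler angles of the hand rotation,
unwrapped along time to avoid ±π jumps. Velocity uses central differences
(one-sided at the ends) at a nominal sampling rate (`fs_equivalent`, default
250 Hz) assigned to the normalised time base; since time normalisation
discards true durations, this rate only scales the velocity PV and cancels
in ΔV.

The three release parameters (angle, speed, height) exist, strictly, only at
the release instant, while the regression needs a per-time-point value. The
package uses instantaneous hand-based analogues in the lab's sagittal
(y–z) plane: speed = |(v_y, v_z)|, angle = atan2(v_z, v_y) in degrees,
height = hand z. These coincide with the ball's release parameters at the
release sample (the last normalised sample). This is the largest
interpretive decision in the package; it is isolated behind
`release_mode="instantaneous"`, and `release_mode="constant"` instead holds
each trial's release-sample value fixed across the whole movement, so both
readings of "the mean-free instantaneous value of the performance variable"
can be compared.

## Kinematic model

A four-segment chain (thorax, upper arm 0.30 m, forearm 0.27 m, hand
0.08 m — plausible adult defaults, configurable and serialisable as JSON)
maps the seven angles to the hand. Axes follow the ISB convention: +z up,
+y anterior (toward the target), +x lateral; the lab origin is the
force-platform centre. The shoulder rotates by an intrinsic ZYZ Euler
sequence, elbow and wrist by intrinsic XYZ Cardan sequences.

Two DOF allocations are plausible for this chain: shoulder 3 / elbow 2 /
wrist 2, or shoulder 3 / elbow 1 / wrist 3. The default is 3/1/3 — matching
the indexing that assigns three angles to the wrist — with forearm
pronation–supination carried as the wrist's axial rotation; the 3/2/2
layout is available via `ArmModel.dof_layout`. The reference pose (all
angles zero) hangs the arm along −z with the hand aligned to the forearm; no
standard zero pose exists for this chain, so this is a documented constant
of the model.

The finite-difference position Jacobian (central differences, default
h = 10⁻⁶ rad, O(h²)) is the ground-truth oracle against which the
regression Jacobian is validated: on ensembles whose performance variable is
an exact linear map the regression recovers the map to machine precision,
and for the nonlinear hand-position map the regression estimate converges to
the finite-difference Jacobian as deviation magnitude shrinks (checked over
2°, 1°, 0.5°).

## Preprocessing

Zero-lag low-pass filtering uses one forward and one backward pass of a
2nd-order Butterworth (effective 4th order), with the design cutoff raised
by (√2 − 1)^(−1/4) ≈ 1.2465 so the −3 dB point of the combined response
sits at the nominal cutoff — the usual biomechanics convention; a 10 Hz
default matches throwing-arm segment data. `order=8` selects the
4th-order-dual-pass alternative. Note the forward–backward pass is
time-reverse symmetric only away from the edge transients, whose initial
conditions swap roles under reversal.

Residual analysis follows Winter's construction: RMS residual between raw
and filtered series over a cutoff grid, a straight line fitted to the
noise-dominated top 40 % of the grid and extrapolated to 0 Hz, and the
lowest grid cutoff whose residual falls to the intercept (ties toward lower
cutoffs). A tolerance of 1 % of the signal RMS absorbs the degenerate
noiseless case where the intercept is ≈ 0; pure noise returns the smallest
grid value, an all-zero series the largest with a warning.

Stride-foot contact is the first sample with vertical ground-reaction force
strictly above 10 N. Movement windows (contact to release) are
time-normalised to 100 samples by cubic spline; the spline is exact on
cubics and preserves the endpoints. Cubic interpolation can overshoot on
ragged monotone inputs, so monotonicity is only guaranteed for adequately
sampled smooth signals — which normalised joint-angle series are after
filtering.

Release parameters come from the scaled, filtered (10 Hz) ball path:
central-difference velocities, speed = √(Vx² + Vy²), angle = atan2(Vy, Vx)
— elevation above horizontal, the reading under which release angle grows
with target distance — and height = filtered y, all at the release frame.
The image-to-lab calibration is a single multiplicative scale, which
commutes with the linear filter, so the order of scaling and filtering is
immaterial.

## Affordance simulation

Ball flight integrates ẍ = −(k/m)·v·vx, ÿ = −g − (k/m)·v·vy with
k = ½ρC_dA by fixed-step classical RK4 (dt = 1 ms; fixed step keeps runs
bit-reproducible; halving dt moves the height at a 10 m plane by < 10⁻⁵ m
over the study's parameter range). Defaults: ITF regulation ball (57.7 g,
67 mm), sea-level air density 1.225 kg/m³, C_d = 0.55 — a typical measured
tennis-ball value, since no standard coefficient attaches to this task.
Setting the drag coefficient to zero reduces the model to the closed-form
ballistic trajectory, which serves as an independent oracle (agreement to
10⁻⁶ m on the sweep grid, asserted at 10⁻⁴ m).

The analysis is two-dimensional (sagittal plane): release parameters carry
no lateral component, so the target's 1.2 m width is not binding and only
its vertical extent (1.2 m centred 1.5 m up) decides hits. A crossing
exactly on the target edge counts as a hit (inclusive boundary, within a
10⁻¹² float guard; flag-switchable). A flight that lands short of the plane
is a miss with reason "short".

## Synthetic data

The generator emulates the statistical structure the estimator assumes, not
throwing biomechanics. Mean trajectories are sums of ≤ 3 sinusoids per
joint over the movement phase (offsets within ±40°, total amplitude 30° by
default) — smooth, anatomically bounded, and with analytically known
curvature for testing, but not modelled on real joint excursions. Trial
deviations at each time point are Gaussian with a prescribed variance per
DOF inside a known null space and its orthogonal complement. Defaults
v_ucm = 4 deg², v_ort = 1 deg² give an unambiguous synergy (analytic
ΔV = 0.84 at d = 1, 1.10 at d = 3) at trial-to-trial angular variability
plausible for a practised throw; no published values exist for this task,
so these are the package's chosen study conditions, fixed once.

Deviations are i.i.d. across time by default, since the estimator treats
time points independently; an AR(1) option (`ar1_rho`) adds temporal
smoothness when the time-series realism matters. Ground-truth basis fields
are the null spaces of the finite-difference kinematic Jacobian along the
mean trajectory, so generator and estimator are consistent by construction.

The study-level generator writes `P{id}/D{distance}/T{trial}.csv` trees
(header `time_pct,q1,...,q7`, degrees) with a per-trial release table and a
manifest of seeds, injected targets and file checksums. Release parameters
per distance jitter around a nominal release solved to pass through the
target centre (angles 6°/12°/18°, heights 1.85/1.90/1.95 m at 5/10/15 m,
speeds from the drag-free trajectory equation; jitter sd 2°, 0.5 m/s,
0.03 m), so release angle, speed and height all grow with distance and the
distance ANOVA has a real effect to find.

What passing tests therefore show: the estimator chain recovers known
injected structure, the algebraic identities hold, and the pipeline's
bookkeeping is correct. What they do not show: robustness to non-Gaussian
deviations, marker noise, soft-tissue artefact, filtering interactions, or
Jacobian nonlinearity at large deviation amplitudes — properties of real
recordings that synthetic Gaussian ensembles cannot certify.

## Statistics

The release-parameter analysis is a one-way within-subject ANOVA (distance:
5/10/15 m) on per-participant trial means. The Greenhouse–Geisser ε̂ comes
from the doubly-centred covariance of condition scores,
ε̂ = tr(S̃)²/((k−1)ΣS̃ᵢⱼ²), clipped to [1/(k−1), 1]; corrected degrees of
freedom are ε̂(k−1) and ε̂(k−1)(s−1), partial η² = SS_cond/(SS_cond+SS_err).
Sphericity is not pre-tested — the correction is applied unconditionally,
which is conservative when sphericity holds and correct when it does not.
Tests compare F and ε̂ against an independent sums-of-squares oracle and
against pingouin, and p-values only loosely (tail precision differs across
F-distribution implementations at extreme values).

## Problem sizes

The validation suite runs at desk scale by choice: identity checks on 100
random ensembles of 10–40 trials; recovery at 500–2000 trials where the
per-DOF variance sampling error (≈ √(2/N) relative at d = 1) leaves wide
margins under the stated tolerances; the full-study pipeline at
7 × 3 × 20 trials (the study design) in the acceptance script and a
2-participant reduction in the test suite. The acceptance script completes
in well under a minute and derives every random stream from its `--seed`.

## Known limitations

- The release-parameter performance variables during the movement are
  hand-based analogues (see above); other operationalisations are possible
  and `release_mode` only covers the two obvious ones.
- No confidence intervals on ΔV (no bootstrap/hierarchical machinery).
- No motor-equivalence or tolerance–noise–covariation decompositions.
- 2D flight only: no spin, Magnus force, wind, or lateral error.
- The kinematic model has no joint limits, scapular rhythm, or inverse
  kinematics from markers; it consumes joint angles, not marker clouds.
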