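# Methods

This note documents the models, conventions, parameter choices and known
limitations of `inertrack`, in the spirit of a statistical package's model
documentation.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Frames, conventions, notation

Quaternions are stored `(w, x, y, z)`, Hamilton product, active rotations;
`q_AB` rotates vectors from frame B into frame A (`v_A = R(q_AB) v_B`).
`qexp` maps half-angle rotation vectors, so `2·qlog(q)` is the rotation
vector of `q`.  The global frame has x along magnetic north and z up,
opposite gravity; `g_G = (0, 0, −9.81) m/s²`, so a static upright IMU
measures `+9.81` on its z accelerometer axis.  Segment frames sit at the
proximal end with z along the bone (`p_prox = 0`, `p_dist = (0,0,L)`); the
"out of bone" direction used for perpendicular calibration errors is
segment x (configurable in principle — the choice is a convention, the
perpendicular direction is not anatomically fixed).

The kinematic chain uses classic Denavit–Hartenberg rows
`Rot_z(θ)·Trans_z(d)·Trans_x(a)·Rot_x(α)`.  Each segment of the arm model
contributes two α-DoF rows (with fixed θ offsets ∓π/2 that cancel at zero
angles), one θ-DoF row, and the bone translation.  At zero angles the chain
points straight up.  Any DH convention that reproduces this initial pose
and the documented peak signal norms is equivalent for every result here;
the convention itself carries no scientific content.

## Measurement models

Per IMU and time step the stack is accelerometer (3), gyroscope (3) and —
when enabled and observable — one scalar magnetometer heading row, i.e.
7 rows with magnetometer and 6 without; joint connectivity adds 3 rows per
joint and the global anchor 3 more.  The magnetometer model compares only
the heading of the globally-rotated field with global x, deliberately
discarding dip-angle information (standard practice to limit the influence
of magnetic disturbances).  If the horizontal projection of the rotated
field drops below 1e−6 the scalar row is undefined (atan2 of ~0/~0) and is
skipped for that step; the simulated field (global x measured in the IMU
frame) never comes close to this in the study motion.

## Synthetic data

The generator emulates ideal strapdown sensors on a rigid three-segment
chain: ground-truth poses from forward kinematics, gyroscope data as
quaternion central differences expressed in the IMU frame, accelerometer
data as `R_GIᵀ(p̈ − g)` with second central differences of the IMU
positions, second-order one-sided schemes at the sequence ends, and a
magnetometer that measures global x exactly.  The excitation
`φ(β) = sin(β/2)·sin(β)·π` over one period in 629 samples of 10 ms reaches
|φ| = 138.6° (the continuous extremum is `4/(3√3)·π`), giving the
documented ±139° range of motion; the same series drives all nine DoFs.

What the generator does **not** emulate: sensor biases and scale factors,
magnetic-field inhomogeneity, soft-tissue motion of the sensors relative to
the bone, sampling jitter, or human-like joint limits.  Passing tests on
this data therefore demonstrate correctness of the estimators and their
relative robustness to *model calibration* errors — not performance on real
recordings.

Calibration-error injection perturbs the model used to *generate* the data
(I2S position shifts along/perpendicular to the bone, bone-length change,
I2S rotations about the bone/about the IMU x-axis) while trackers receive
the nominal model.  Because translations never rotate anything and I2S
errors never move segments, the ground-truth segment orientations are
identical with and without injection, so errors are always measured against
the unperturbed truth.  The segment-length error is applied on the
simulation side (uniformly with the other four types): note that it leaves
the middle IMU's own data untouched and enters through the distal chain.

Sensor noise is i.i.d. zero-mean Gaussian per channel (defaults
σ_gyro = 0.01 rad/s, σ_acc = 0.05 m/s², σ_mag = 0.01 with renormalization),
reproducible from a seed.  The headline results use noise-free data, where
the influence of calibration errors can be studied in isolation.

## Initialization

All trackers share one initialization.  TRIAD on the first sample gives
per-IMU attitudes; inverse kinematics fits chain angles to them.  Plain
TRIAD is exact only at rest, and the study sequence does *not* start at
rest (`φ̈(0) ≈ π rad/s²` per DoF): body acceleration tilts the first-sample
specific force by up to 34° at the distal IMU.  That bias matters little
with a magnetometer but is fatal without one, because the global yaw is
exactly unobservable and a transient attitude excursion freezes into a
permanent offset.  The initialization therefore refines the full initial
chain state (angles, rates, angular accelerations, constant over the first
three samples) by a small least squares fit that explains the first
accelerometer/gyroscope samples through the chain model, with weak priors
(angles near the TRIAD/IK fix at 45°, rates shrunk toward zero at
20 rad/s and 200 rad/s²) and a soft-L1 loss so that data from a
miscalibrated IMU — an outlier against the consistent majority — does not
drag the fit.  The magnetometer seeds the initial heading whenever the
channel exists, even when the tracking-time magnetometer model is disabled;
otherwise a configured yaw is assumed.  Segment placement from the anchor
outward satisfies the joint constraints exactly.

## EKF trackers

Quaternions stay in the state at four components but the covariance lives
on a 3-DoF multiplicative attitude error (`q = q̂ ⊙ exp(δ/2)`), avoiding
the rank deficiency of a four-component covariance.  Dynamics:

* `QuattrackerIMU`: constant angular velocity, constant linear
  acceleration (`q⁺ = q ⊙ exp(T/2·ω)`);
* `QuattrackerSegment`: constant angular acceleration
  (`q⁺ = q ⊙ exp(T/2·ω + T²/4·ω̇)`), with the accelerometer prediction via
  rigid transport `a_I = S̈ + R_GS[S(ω)S(ω) + S(ω̇)] r_IS`;
* `Chaintracker`: per-DoF constant angular acceleration (exactly linear
  transition).

Process noise drives the highest derivative of each model: σ_jerk =
200 m/s³ on linear acceleration (entering as `T·σ` per step), σ = 100
rad/s² on the IMU filter's angular velocity, 20 rad/s² per step on the
segment filter's angular acceleration, 5 rad/s² per step per DoF for the
chain.  Measurement noise defaults: σ_acc = 0.5 m/s², σ_gyro = 0.02 rad/s,
σ_mag = 5°, σ_joint = σ_anchor = 1 mm.  These are engineering defaults for
the study motion, all overridable; they trade responsiveness against
smoothness and were chosen so all three filters are stable with and without
magnetometer on the study sequence.

Measurement Jacobians are analytic for the two free-state filters (each is
verified against central differences in the suite) and batched central
differences for the chain filter, whose measurement prediction
differentiates the forward kinematics over a virtual time step (h = 1 ms):
poses at `θ ∓ h·θ̇ + h²/2·θ̈` yield the IMU angular velocity and linear
acceleration to O(h²) without analytic chain Jacobians.  Constraints are
stacked with the sensor rows in a single update (one linearization point);
the covariance update uses the Joseph form and is symmetrized, and positive
semi-definiteness is checked.

## Sliding-window optimizer

Each batch estimates, for every window step, every IMU pose+velocity *and*
every segment pose (15 error-DoF per segment per step).  Residual blocks:
calibration orientation `2·log(q_SI* ⊙ q_SG ⊙ q_GI)` and position
`I − (S + R_GS r_IS)`; strapdown motion terms with the IMU data as control
inputs; soft joint constraints; the anchor; the low-weight magnetometer
heading; and an arrival term tying the first window step's IMU orientations
to the previous batch.  Two numerical points matter:

* **Trapezoidal integration.**  The motion terms integrate the control
  inputs trapezoidally (`e_q = 2log(q'* q exp(T/4(y_ω + y_ω')))`, velocity
  and position analogously).  Explicit Euler leaves an O(T²·ω̇) model error
  (~1° at the study's rates) that visibly biases the optimum on data
  produced by central differencing; the trapezoid reduces it to O(T³).
* **Damped Gauss–Newton with a floor.**  Without a heading reference the
  problem has an exact global-yaw null space; an undamped normal-equations
  solve would wander along it.  Marquardt scaling with a small damping
  floor keeps the step minimum-norm.  Analytic block-sparse Jacobians (with
  closed-form inverse SO(3) Jacobians on the log-residuals) and a sparse
  Cholesky solve make a window solve a few milliseconds.

Weights (standard deviations): σ_cq = 0.15 rad, σ_cp = 1.0 m,
σ_p̂ = 1 mm, σ_p̂̇ = 0.05 m/s, σ_q̂ = 1 mrad, σ_anchor = σ_joint = 1 mm,
σ_mag = 0.5 rad, σ_q0 = 0.01 rad (0.5 rad for the first batch).  The very
loose calibration-position weight is deliberate and load-bearing: the I2S
position is the least reliable model parameter (there is no established
calibration method for it), and a tight weight lets position
miscalibration distort the *orientation* estimates by many degrees,
destroying precisely the robustness this estimator is chosen for.  The
calibration-orientation weight stays moderately tight so each segment's
twist follows its IMU — which is also why an injected I2S orientation
error propagates (linearly, as it should) into the affected segment while
its neighbors merely translate.

The window slides with overlap `ov` (`ov = w−1` is moving-horizon,
`ov = 1` advances `w−1` samples per solve); each step is emitted exactly
once, from the last window containing it.  The first batch is longer
(`init_batch = 500` samples by default) and its arrival term is weak:
sliding windows *maintain* consistency but cannot repair an initialization
bias, so the initial transient must be resolved while the whole early
history is still in view.  The default window is w = 30, ov = 29; the
evaluation suite uses ov = 1 (identical estimates on noise-free data,
verified by an overlap-invariance test) to keep runtimes down.

## Evaluation

Angular error per segment and step: `E = 2·acos|(q̄ ⊙ q*)_w|` in degrees
(the absolute value handles the quaternion double cover; without it,
sign-flipped quaternions could yield angles beyond 180°).  Statistics over
K segments and N steps: mean of per-segment time means; mean of per-segment
temporal standard deviations (N−1 denominator; a pooled-s.d. reading of the
aggregate is possible but not used); overall maximum.  The normalized range
error sums a tracker's mean errors over one error type's grid and divides
by the reference tracker's (the chain EKF's) worst-case sum over all tests.
The sweep grid excludes zero: ±2°…±30° in 2° steps (30 values) per
rotational type, ±0.02…±0.2 m in 0.02 m steps (20 values) per translational
type — 120 evaluations per tracker and condition.  The "without
magnetometer" condition disables the magnetometer measurement model in the
tracker configuration while the channel stays in the dataset to seed the
initial heading.

## Problem sizes in the test suite

The suite runs the full 629-sample sequence for the headline checks; unit
tests use a 160-sample slice.  The optimizer invariance tests evaluate the
extreme grid magnitudes (±0.2 m, ±30°) rather than all 120 grid cells, and
the EKF propagation tests use δ ∈ {10°, 20°, 30°}; `run_sweep()` supports
the complete grid for standalone studies.  Regression bounds on tracker
accuracy are frozen from reference runs of this implementation.

## Known limitations

* No sensor-bias or scale-factor states; biased gyroscopes will drift the
  EKFs in yaw without a magnetometer.
* All joints are modelled with three DoF; restricted joints (hinges) and
  joint-limit priors are out of scope.
* The chain EKF assumes the tree/chain topology is exact; it has no
  mechanism to absorb calibration errors (which is the point of the study).
* The constant-angular-velocity model of the IMU-centered EKF lags under
  sustained angular acceleration; on the aggressive artificial sequence it
  is the least accurate of the four methods here, and the segment-centered /
  chain orderings depend on tuning and on how well each motion model fits
  the particular motion.
* The optimizer's accuracy advantage relies on consistent, low-noise
  gyroscope data (tight σ_q̂); with real sensors those weights must be
  re-tuned to the noise level, and the mean error grows accordingly.
* Magnetic disturbance simulation (inhomogeneous fields) is not included;
  the artificial magnetometer is ideal.
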