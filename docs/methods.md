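# Methods

## Models

The standing body is modelled as planar inverted pendulums on a
horizontally translating support, with the feet rigid on the platform
and posture angles small. Coordinates: $+x$ forward, $+y$ left, $+z$
up; plate moments are right-handed about the plate axes, which makes the
moment term $-N_y$ in the sagittal equations and $+N_x$ in the frontal
ones. COM displacements are expressed in the moving (platform) frame;
the support acceleration enters the equations as an inertial forcing
term measured in the stationary frame.

Three model variants are used:

* **Sagittal single pendulum** — everything above the ankle is one rigid
  body (mass $m_b$, COM height $l_b$, inertia $J_b$ about its COM; the
  whole-body inertia symbol in the moment equation is identified with
  the tabulated $J_b$, since no separate value exists).
* **Sagittal double pendulum** — lower body (ankle to hip) and upper
  body (hip upward), with the head sensor at distance $L_2$ above the
  hip on the upper segment.
* **Frontal loop** — two parallel legs, a pelvis that *translates
  without rotating* (the loop closure with parallel legs prevents pelvic
  rotation), and an upper body rotating about the waist. Because the
  pelvis only translates, the upper-body lever per unit common tilt is
  $L_l + l_u$ (not $L_l + L_p + l_u$), while its moment arm *height* is
  $L_f + L_l + L_p + l_u$. With the tabulated coefficients the identity
  $J_{y1} l_l + J_{y2}(L_l + l_u) = J_{yb}\, l_b$ holds exactly, i.e.
  the loop collapses consistently onto its constrained single pendulum;
  the test suite asserts this.

Anthropometry is regression-based: masses $\propto M$, lengths
$\propto H$, inertias $\propto MH^2$, with coefficients fixed in
`anthropometry.py`. The mass coefficients close exactly
($0.322+0.656 = 0.978$; $2\cdot0.161+0.187+0.469 = 0.978$). The length
and inertia coefficients are independently rounded, so the
segment-weighted COM height agrees with $l_b$ only to ~0.1–0.6%; the
package uses the tabulated values verbatim and the tests assert the
closure at the 1% level *without* expecting exactness. One consequence:
Methods I and II agree bit-for-bit on in-phase motion only under a
self-consistent parameter set (tested by recomputing $l_b$, $J_b$ from
the segment rows); with the verbatim table the discrepancy is ~0.05% of
the inertial term, far below sensor noise.

## Estimators

**Method I** solves the two single-pendulum equations per sample for
$\ddot x_b$ (from the horizontal force) and $x_b$ (from the moment).
**Method II** solves the 3×3 system (force balance, moment balance, head
kinematic constraint) for $(\ddot x_1, \ddot x_2, x_b)$; the matrix is
time-invariant, so one LU factorisation is reused across all samples,
and a condition number above $10^{12}$ is rejected. The COM
acceleration is the mass-weighted segment combination. For the frontal
plane, the first matrix row carries the pelvis lever factor
($2m_l + m_p L_l/l_l$), consistent with the acceleration weights — the
pelvis rides on the hip point.

**Kalman fusion** (Methods I/II only): state $(x_b, \dot x_b)$,
transition $A = [[1, \Delta t], [0, 1]]$, input vector
$b = [\Delta t^2/2, \Delta t]$ driven by the estimated acceleration,
observation $c = [1, 0]$ on the estimated displacement. Design
parameters $Q_w = \mathrm{diag}(0.0025, 0.04)$, $Q_v = 1$ are expressed
in the working unit, millimetres, where $Q_v = 1\,$mm² is a plausible
displacement-observation noise; SI values are converted in and out
centrally. Initialisation: $\hat x_0 = (y_0, 0)$,
$P_0 = \mathrm{diag}(Q_v, 100\,Q_{w,22})$; the 5 s head-cut of the
evaluation window absorbs the transient. Non-finite input samples
produce NaN outputs at those samples while the recursion coasts on
prediction. The covariance is re-symmetrised each step; tests verify
symmetry and positive semidefiniteness over $10^5$ random steps and that
the steady-state first gain component lies in $(0,1)$.

**Baselines.** Method III low-passes the COP (zero-phase Butterworth,
default cutoff 0.5 Hz, order 8) — the cutoff is this package's choice of
a standard literature formulation, exposed in config. Method IV
integrates $\ddot x_b = (-M\ddot X_s - R_x)/m_b$ twice (cumulative
trapezoid), applying a zero-phase 0.1 Hz high-pass after each
integration to bound drift; integration constants are zero. COP is
computed as $N_y/F_z$ and $-N_x/F_z$ with an optional plate-surface
height correction ($z_0 = 0$ by default: moment reference on the
surface).

## Signal conditioning

Horizontal plate forces are high-passed at 0.1 Hz (8th-order Butterworth
applied forward–backward — the order is per pass, so the effective
attenuation is the squared response; the convention is configurable).
Edge handling uses mirror (even) extension with padding of about three
filter time constants: on 40 s records, whose length is only a few
cutoff periods, this leaves an order of magnitude less interior edge
transient than odd extension — measurable on the support-sway trials,
whose excitation extends down to 0.05 Hz. Moments and the vertical load
are not filtered.

The head IMU yields horizontal acceleration in three steps: (1) attitude
tracking by a quaternion EKF — gyro propagation of the orientation, a
3-state body-frame attitude-error covariance, and a gravity-direction
update from the accelerometer with a deliberately large measurement SD
(2 m/s²) so horizontal motion barely tugs the attitude (correction time
constant of order 100 s); (2) rotation of the specific force to the
stationary frame and subtraction of gravity (magnitude estimated from a
1 s quiescent lead-in); (3) the horizontal components are returned. The
initial attitude comes from averaging *gyro-de-rotated* accelerometer
samples over the whole record: processing is offline, and bounded sway
means the record-mean horizontal acceleration is near zero, so this
pins the initial tilt to sub-milliradian accuracy even though the
subject moves. Gyro bias is not estimated and yaw is unobservable and
unused — design choices, since only the EKF's existence, not its
structure, is prescribed. Records whose accelerometer norm deviates
from gravity by more than 50% are rejected as attitude-unreliable.

Numerical differentiation is second-order central differences with
one-sided ends (`np.gradient`).

## Simulator

The generator *defines* the study conditions; its defaults are fixed
and the tests run against them.

* **Trajectories.** All angle series are analytic harmonic sums with
  closed-form derivatives, multiplied by a raised-cosine on/off envelope
  (2 s ramps) via the product rule — ground truth is therefore
  kinematically consistent to machine precision. Quiet standing is
  band-limited (0.05–1.0 Hz, spectrum rolled off above 0.3 Hz) seeded
  random-phase sway at 0.003 rad RMS, giving ~3 mm COM sway; a smaller
  independent upper-body component (2/3 of the common RMS) reflects
  that real sway is never a perfect single pendulum. Ankle motions:
  0.04 rad in-phase sinusoid at 0.25 Hz. Hip motion: counter-phase
  $\theta_2 = -2.0\,\theta_1$ at 1 Hz, $\theta_1$ amplitude 0.025 rad —
  the ratio sits below the exact COM-cancellation value (~3.14 for
  these segment parameters) so the true COM still moves a few
  millimetres while segment accelerations exceed 100 mm/s², matching
  the hip-strategy regime (and perfect cancellation would make every
  channel a scalar multiple of one sinusoid, degenerating all
  correlations to ±1). Support sway: 20 equal-amplitude harmonics at
  0.05–1.0 Hz in 0.05 Hz steps with seeded phases, scaled to 0.02 m RMS;
  only the spectrum is contractual, the phase realisation is
  seed-random.
* **Linear inverse dynamics** substitutes the trajectories into the
  linear models forward — a code path deliberately separate from the
  estimators, so round-trip recovery is a genuine inversion test, exact
  to ~1e-15 m.
* **Nonlinear oracle** (`nonlinear.py`): exact planar Newton–Euler
  reaction wrench via sympy — positions written as trig functions,
  accelerations by symbolic differentiation, force from the momentum
  theorem, moment from the inertial-minus-gravity wrench about the plate
  origin; feet (mass $M - m_b$) ride on the plate at half ankle height.
  It also produces the exact head-point acceleration and ideal IMU
  channels (specific force including gravity, body rates). Validation
  does not reuse the oracle's own algebra: tests re-derive segment
  positions independently and check that the reaction force equals the
  finite-difference derivative of total linear momentum (an energy-based
  audit is not available because prescribed trajectories imply joint
  torques that do work). Linear and nonlinear generators agree in the
  small-angle limit with the expected super-quadratic error collapse.
* **Noise**: seeded Gaussian per channel (defaults: 0.1 N forces, 0.05
  N·m moments, 0.5 N vertical, 0.005 m/s² support, 0.01 m/s²
  head/IMU accelerometers at sensor-grade noise density, 0.002 rad/s
  gyro), optional force drift ramp, and an optional fractional-sample
  delay of the head stream (interpolation on the common grid) to model
  device-synchronisation error.

What the simulator does *not* emulate: closed-loop balance control (the
motions are prescribed, not feedback-generated), vertical COM motion in
the linear models, soft-tissue artefacts, force-plate low-frequency
drift structure beyond a linear ramp, and IMU scale/bias errors.
Passing tests therefore demonstrate correctness of the inversions,
fusion and metrics under the stated models and sensor-noise levels — not
performance on any particular human cohort.

## Evaluation

RMSE and Pearson correlation are computed on the half-open window
[5 s, 35 s), which at 100 Hz is exactly 3000 samples; both metrics use
the same window (correlation-window placement is not separately
specified anywhere, so same-window is this package's documented
reading). $C_p$ is the windowed correlation between the COP and the
Method-I displacement; the gate threshold 0.8 is a config default.
Zero-variance windows raise rather than silently returning zero.

## Numerical choices and degenerate inputs

Uniform-grid validation rejects gaps larger than 1.5 sampling intervals
(naming the row). Segment masses and inertias may be zero (degenerate
models are useful in tests) but lengths must be strictly positive;
subjects must have finite positive mass and height. CSV output uses 17
significant digits and round-trip float parsing, so write/read is
value-exact and repeated runs are byte-identical. The acceptance script
derives every random stream from the single `--seed` argument.

## Known limitations

The anthropometric table targets young adult males; child, elderly and
female populations would need different regressions. Vertical motion
(hip/knee flexion) is outside the linear models. Method III/IV cutoffs
are standard literature choices, not tuned to any particular dataset.
The attitude EKF assumes a roughly level, low-dynamics head sensor; it
is not a general orientation tracker. Problem sizes in tests and the
acceptance script (40 s at 100 Hz, single subject, fixed seeds) are the
package's chosen synthetic study design.
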