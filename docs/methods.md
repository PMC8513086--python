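# Methods

This note records the models implemented in `gaitfuse`, the assumptions they
make, the defaults and why, and the numerical choices a maintainer would
want explained.

## Conventions

Quaternions are scalar-first `(w, x, y, z)` Hamilton quaternions; `R(q)`
rotates body-frame vectors into the world frame. Euler angles are intrinsic
Tait-Bryan ZYX (yaw-pitch-roll): the pitch term is an arcsine, confined to
[−90°, 90°], and its argument is clipped to [−1, 1] to absorb floating-point
overshoot near gimbal lock. Angles are radians internally and degrees at
every user-facing boundary. The world frame is z-up: gravity reference
(0, 0, 1) in units of g, magnetic reference a unit vector with a 60°
mid-latitude dip, `(cos 60°, 0, −sin 60°)`.

The **two-quadrant constraint** takes the component-wise absolute value of
the quaternion. It is applied to both series before any component-wise
comparison of estimates against a reference: a quaternion reconstructed from
its own Euler angles is unique only up to global sign (and the arcsine
branch folds further signs), so unconstrained component RMSE conflates
representation ambiguity with estimation error. A `vector_only` switch
restricts the rectification to (x, y, z); the all-four default is idempotent
and sign-symmetric. Under the constraint the quaternion → Euler → quaternion
round trip is loss-free to machine precision (the suite checks component
RMSE < 1e−6 over 10,000 random orientations; measured ≈ 1e−16).

## Orientation observer

One accelerometer/magnetometer pair determines orientation by minimising the
stacked residual

    f(q) = [ R(q)ᵀ(0,0,1) − a ;  R(q)ᵀ(bₓ,0,b_z) − m ],

`a`, `m` normalised. The magnetic reference `(bₓ, 0, b_z)` is recomputed
from the current estimate (fold the world-frame horizontal component onto
x), which removes sensitivity to local declination. Assumptions: the
accelerometer reads gravity only (slow motion), and the field is spatially
uniform.

Two minimisers share the analytic 6×4 Jacobian (verified against central
finite differences at 1e−5):

* **Gradient descent**: `q ← normalize(q − μ Jᵀf)`, μ = 0.01, up to 500
  iterations, stopping when ‖Jᵀf‖ < 1e−6. The fixed step needs ~450
  iterations to bring a 20° cold-start error under 0.5°, hence the budget;
  inside filters the observer is warm-started from the previous estimate
  and converges far faster.
* **Gauss-Newton**: the step solves the ridge normal equations restricted to
  the tangent space of the unit sphere (`P = I − qqᵀ`, `A = JP`), with an
  adaptive Levenberg damping term (a step must not increase the residual
  against the current magnetic reference) plus a constant 1e−8 ridge for the
  rank deficiency. The tangent restriction is essential, not cosmetic: the
  raw 4-space Gauss-Newton step is dominated by its radial component, which
  renormalisation cancels — measured stalls ranged up to 90° from cold
  starts. The tangent-space form converges in ≤ 10 iterations on a 20° tilt
  and to < 0.002° worst-case over wide random cold starts.

With no magnetometer the observer runs gravity-only; yaw is then
unobservable and stays near the seed's yaw (degraded mode, drifting a few
degrees as roll/pitch are corrected).

## Fusion filters

All filters integrate the gyro rate `q̇ = ½ q ⊗ (0, ω)` with first-order
steps `normalize(q + q̇Δt)`, per-sample Δt from the timestamps (wireless
streams jitter). First output = the configured initial orientation, identity
`[1, 0, 0, 0]` by default — estimates therefore show a convergence transient,
which is why accuracy metrics discard a 5 s burn-in. At 75 Hz and the
~330°/s peak rates of the default gait program the first-order
discretisation leaves an irreducible tracking floor of ~1–2° mean geodesic
error even on noiseless data; this is a property of the update form, not of
the noise handling, and the test bounds reflect it.

* **Complementary**: blend `α·q_gyro + (1−α)·q_obs`, renormalised; the
  observer output is hemisphere-aligned to the gyro prediction (negated when
  the dot product is negative) so the linear blend cannot cancel. Blending
  is linear in components, not spherical: at 75 Hz the per-sample angular
  separation is tiny and the renormalised linear blend is
  indistinguishable from geodesic interpolation.
* **Kalman**: state = quaternion, `F = I + ½Ω(ω)Δt`,
  `Q = β·σ²_gyro·Δt²·I` with σ²_gyro from a static window
  (`static_gyro_variance`, default 1e−4 rad²/s² when none is supplied),
  measurement = hemisphere-aligned observer quaternion with `H = I` and
  `R = 1e−2·I`, covariance symmetrised each step with an eigenvalue floor as
  a guard (never triggered in the suite, which checks symmetry and positive
  semi-definiteness over 10,000 noisy steps).
* **Madgwick**: `q ← normalize(q + (q̇_ω − β·∇f/‖∇f‖)Δt)`, β = 0.1 rad/s.
  The gradient is only normalised when its norm exceeds 1e−12: at an exactly
  consistent estimate the residual is pure round-off, and normalising it
  would blow numerical noise up to a unit-length correction.

Defaults (α = 0.98, Madgwick β = 0.1, Kalman β = 1.0) are deliberately
generalist and all config-exposed; no per-filter tuning is attempted.
Setting α = 1, β = 0, or Q = 0 with perfect initialisation reduces every
filter to identical pure gyro integration (checked to 1e−9).

Gyro units (`deg/s` vs `rad/s`) can be declared or auto-detected; the
heuristic treats a stream as deg/s when the 95th-percentile magnitude
exceeds 20, far above sustained human angular rates in rad/s.

## Calibration and conditioning

Static calibration low-pass filters the first 5 s (count-based: 375 samples
at 75 Hz) and removes the window mean from gyro channels. For the
accelerometer, the expected gravity vector of the static pose — +1 g on the
axis with the largest mean magnitude, signed to match — is preserved and
only the residual treated as bias: removing the raw mean would delete
gravity and break the observers. Magnetometer hard-iron calibration centres
each axis at (max + min)/2 over a full-rotation maneuver and scales
half-ranges to their mean; soft-iron handling is deliberately limited to
this per-axis scaling (the maneuver described cannot constrain a full
ellipsoid). The low-pass is a zero-phase 4th-order Butterworth, default
cutoff 10 Hz at 75 Hz sampling — well above the < 6 Hz gait band.

## Joint angles and cycle analysis

Default joint-angle mode is the per-plane difference of the two segments'
Euler angles, with flexion-extension mapped to pitch (hinge about the
mediolateral y axis); a relative-quaternion mode
(`euler(q_proximal* ⊗ q_distal)`) is provided and cross-checked (the two
agree within 1° on hinge-dominated motion, and exactly on a pure hinge).

Cycle extraction cuts the angle curve at successive rising crossings of a
threshold, drops cycles outside [0.5, 1.5]× the median length (a minimal
robustness gate), and linearly resamples each cycle to 101 points (0–100 %
inclusive, the standard gait-percentage convention). Statistics: per-cycle
ROM = max − min of the resampled cycle; `average_rom`, sample-sd `rom_sd`,
`rom_max`; `ci95 = 1.96·rom_sd` (normal-approximation half-width — chosen
because it reproduces standard CI-from-sd summary tables exactly);
pointwise mean/sd curves; global raw extremes; and a least-squares
polynomial of the mean curve (default degree 9, configurable) whose dense
extremes give noise-suppressed ROM bounds together with R².

A known behaviour is inherited by design: because the boundary rule is
angle-based rather than event-based, a mid-range threshold can start cycles
in the swing phase, visually inverting the gait-phase convention. The
crossing phase is recorded on the result (`crossing_phase`) so the artifact
is detectable; it does not change ROM statistics.

Error metrics: `rmse = sqrt(mean((a−b)²))` and
`mape = 100·mean(|a−b|/|a|)` with reference entries |a| < 1e−9 excluded and
counted; multi-channel inputs return per-channel values plus their mean.

## Synthetic data generator

The simulator emulates a robotic-gait-trainer trial: a thigh segment
oscillating in pitch (default 45° peak-to-peak) composed with a knee flexion
program (default 60° peak-to-peak, 1 Hz cadence, 75 Hz sampling, cosine
waveform starting at neutral; a double-peak waveform mimicking the
physiological two-lobe knee curve is available). Both rotations share the
hinge axis, so the commanded knee angle equals the pitch difference exactly
and body rates have closed form — the generator is an exact oracle for the
whole pipeline. The inverse sensor model rotates gravity and the field into
the body frame and adds seeded Gaussian noise and constant biases. Default
test noise (gyro 0.3°/s, accel 0.005 g, mag 0.3 field units) sits at the
optimistic end of consumer MEMS performance.

What the generator does **not** model — and what passing tests therefore do
not show about real recordings: linear (translational) acceleration of the
segments (neglected by default so the accelerometer assumption is exactly
satisfiable; an additive term can be enabled for stress tests), soft-tissue
artifact, magnetic disturbance indoors, sensor-to-segment misalignment, and
sampling jitter. Accuracy on real gait data will be worse than the synthetic
figures, primarily due to soft-tissue motion and magnetic non-uniformity.

## Problem sizes and determinism

The validation suite simulates 60 s trials at 75 Hz (4,500 samples per
segment) for end-to-end checks and shorter 10–30 s trials for unit-level
properties; random draws are seeded everywhere (generator seeds, observer
problem sets, hypothesis derandomised), making every test and the
acceptance script bit-reproducible for a fixed seed.

## Known limitations

* First-order rate integration bounds noiseless tracking at ~1° mean
  geodesic error for the default gait program; an exponential-map
  integrator would remove this floor but is outside the implemented
  filter formulations.
* The Kalman filter treats the observer quaternion as a linear measurement
  with fixed R; no adaptive measurement trust.
* MAPE on quaternion components is dominated by components near zero even
  with masking; RMSE is the primary metric.
* Cycle extraction is angle-threshold based; it inherits the phase-inversion
  behaviour described above and does not detect temporal gait events.
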