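# gaitfuse

Joint-angle estimation from wearable inertial sensors: quaternion sensor
fusion, calibration, and gait-cycle analysis in one tested Python package.

Clinicians and movement scientists increasingly replace optical motion
capture with 9-axis IMUs (accelerometer + gyroscope + magnetometer) strapped
to body segments. Getting from raw sensor streams to a knee flexion-extension
curve requires a chain of non-trivial steps — sensor calibration, orientation
estimation by sensor fusion, relative joint angles, and cycle-by-cycle ROM
statistics. `gaitfuse` implements that chain end to end and ships a
two-segment hinge-gait simulator so every stage can be validated against
known ground truth.

## The estimation problem

Each sensor's orientation is a unit quaternion `q = (w, x, y, z)` evolving as

    q̇ = ½ q ⊗ (0, ω)

with `ω` the body angular rate from the gyroscope. Integrating `ω` alone
drifts; the accelerometer (which measures the gravity direction when motion
is slow) and magnetometer (which measures the Earth field) anchor the
low-frequency orientation. The anchor is a nonlinear least-squares problem:
find `q` minimising

    f(q) = [ R(q)ᵀ (0,0,1) − a ;  R(q)ᵀ (bₓ,0,b_z) − m ]

solved here by fixed-step Gradient Descent or by damped Gauss-Newton
restricted to the tangent space of the unit sphere. Three fusion filters
combine the gyro propagation with this anchor:

* **Complementary** — `q ← normalize(α·q_gyro + (1−α)·q_observer)`, default α = 0.98
* **Kalman** — 4-state quaternion filter; prediction `F = I + ½Ω(ω)Δt`, the
  observer quaternion as measurement, process noise scaled by the static-pose
  gyro variance
* **Madgwick** — `q ← normalize(q + (q̇_ω − β·∇f/‖∇f‖)Δt)`, default β = 0.1

Joint angles are the per-plane difference of the two segments' Euler angles
(intrinsic ZYX; flexion-extension in the sagittal plane). Gait cycles are cut
at rising threshold crossings, resampled to a 0–100 % grid, and summarised as
`average ROM ± sd`, `CI95 = 1.96·sd`, raw and polynomial-fitted extremes.

## Worked example

Simulate ten seconds of a 60° knee program at 75 Hz with low sensor noise,
fuse both segments with the Madgwick filter, and extract gait cycles:

```sh
gaitfuse simulate --duration 10 --gyro-sd 0.2 --accel-sd 0.005 --mag-sd 0.2 \
         --seed 7 --out-prefix trial
gaitfuse fuse trial_proximal_imu.csv --filter madgwick --out est_p.csv
gaitfuse fuse trial_distal_imu.csv   --filter madgwick --out est_d.csv
gaitfuse angle est_p.csv est_d.csv --out ang.csv
gaitfuse cycles ang.csv --out cyc.csv
```

which prints

```
  ROM Max  Average ROM       sd   CI 95%       Min       Max   Min Est   Max Est  Variance      R^2  Cycles  Threshold Crossing
61.012378    60.582559 0.316641 0.620616 -0.576644 60.741653 -0.192468 60.383436  0.100262 0.999999       9  30.082504   rising
```

Nine complete cycles were found; the estimated flexion-extension range of
motion averages 60.6° against the 60° command, with a 0.3° cycle-to-cycle
standard deviation (CI95 = 1.96 × 0.32 = 0.62°). `Min Est`/`Max Est` are the
extremes of a degree-9 polynomial fit to the mean cycle (R² ≈ 1), a
noise-suppressed alternative to the raw extremes. Comparing an estimate with
the simulator's truth stream:

```sh
gaitfuse compare est_d.csv trial_distal_truth.csv
```

reports per-component and average quaternion RMSE / MAPE.

The same operations are available as a library
(`gaitfuse.run_filter`, `gaitfuse.joint_angles`, `gaitfuse.pattern_extraction`, …);
the CLI is a thin wrapper.

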