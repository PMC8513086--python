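import numpy as np
import pytest

import gaitfuse as gf


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_gait():
    """60 s two-segment hinge trial, no sensor noise (distal segment)."""
    program = gf.MotionProgram(rom=60.0, cadence=1.0, duration=60.0, fs=75.0)
    traj = gf.hinge_trajectory(program)
    imu = gf.imu_from_orientation(
        traj.q_distal, program.fs, omega_body=traj.omega_distal, t=traj.t
    )
    return traj, imu


@pytest.fixture(scope="session")
def noisy_gait():
    """15 s hinge trial with realistic low noise (distal segment)."""
    program = gf.MotionProgram(rom=60.0, cadence=1.0, duration=15.0, fs=75.0)
    traj = gf.hinge_trajectory(program)
    noise = gf.NoiseModel(gyro_sd=0.3, accel_sd=0.005, mag_sd=0.3, seed=77)
    imu = gf.imu_from_orientation(
        traj.q_distal, program.fs, noise, omega_body=traj.omega_distal, t=traj.t
    )
    return traj, imu
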