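"""Shared independent reference implementations for the test suite."""

import numpy as np

from gaitfuse.io import ImuSeries
from gaitfuse.quat import gyro_rate_quaternion, quat_normalize


def pure_gyro_integration(series: ImuSeries, q0=None):
    """Reference strapdown integration: q <- normalize(q + 0.5 q⊗(0,w) dt)."""
    q = np.array([1.0, 0, 0, 0]) if q0 is None else np.asarray(q0, float)
    out = [q]
    omega = np.radians(series.gyro) if series.gyro_units == "deg/s" else series.gyro
    for i in range(1, len(series)):
        dt = series.t[i] - series.t[i - 1]
        q = quat_normalize(q + gyro_rate_quaternion(q, omega[i]) * dt)
        out.append(q)
    return np.asarray(out)
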