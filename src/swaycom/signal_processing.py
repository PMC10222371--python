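"""Sensor-stream conditioning.

Zero-phase Butterworth filtering (forward-backward, so the magnitude
response is the squared design response and the phase is identically
zero), numerical differentiation, and conversion of raw head-IMU channels
to horizontal head acceleration in the stationary frame via a
quaternion attitude EKF with gravity-direction correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .series import HeadAcceleration, ImuSeries

__all__ = [
    "zero_phase_butterworth",
    "differentiate",
    "AttitudeEkfConfig",
    "imu_horizontal_acceleration",
]

#: defaults mirroring the conditioning chain: 0.1 Hz high-pass on horizontal
#: forces, 3.0 Hz low-pass on reference kinematics, 8th-order designs.
HIGHPASS_HZ = 0.1
REFERENCE_LOWPASS_HZ = 3.0
FILTER_ORDER = 8


def zero_phase_butterworth(
    x: np.ndarray, fs: float, fc: float, order: int = FILTER_ORDER, mode: str = "high"
) -> np.ndarray:
    """Forward-backward Butterworth filter (zero phase).

    ``order`` is the per-pass design order; the double pass squares the
    magnitude response.  The series is extended by reflection at both ends
    (scipy's odd-padding default) before filtering.
    """
    x = np.asarray(x, dtype=float)
    if mode not in ("high", "low"):
        raise ValueError("mode must be 'high' or 'low'")
    if not 0.0 < fc < fs / 2.0:
        raise ValueError(f"cutoff {fc} Hz must lie in (0, fs/2) = (0, {fs / 2.0})")
    sos = signal.butter(order, fc, btype=mode, fs=fs, output="sos")
    # settling length of the forward-backward pass; require 3x for stable edges
    min_len = 9 * (2 * sos.shape[0] + 1)
    if x.size < min_len:
        raise ValueError(
            f"series of length {x.size} too short for stable zero-phase filtering; "
            f"need at least {min_len} samples"
        )
    # mirror (even) extension up to ~3 filter time constants: for records a
    # few cutoff periods long it leaves an order of magnitude less edge
    # transient in the record interior than the default odd extension
    padlen = int(min(x.size - 1, max(3 * (2 * sos.shape[0] + 1), 3.0 * fs / fc)))
    return signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def differentiate(x: np.ndarray, fs: float) -> np.ndarray:
    """Numerical derivative: central differences interior, one-sided ends."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("differentiate needs at least 3 samples")
    return np.gradient(x, 1.0 / fs)


# ---------------------------------------------------------------------------
# IMU attitude estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttitudeEkfConfig:
    """Design parameters of the attitude EKF.

    The filter state is the orientation quaternion (body -> world); the
    covariance is kept on the 3-component body-frame attitude error.  The
    gravity-direction update uses the accelerometer with a deliberately
    large measurement standard deviation ``sigma_acc`` so that horizontal
    motion acceleration barely perturbs the attitude (the correction time
    constant is of order sigma_acc/(g*sigma_gyro*fs) seconds).  Gyro bias
    is not estimated; yaw is unobservable without a magnetometer and is
    not needed for planar horizontal acceleration.
    """

    sigma_gyro: float = 0.002  # rad/s, gyro white-noise level driving P
    sigma_acc: float = 2.0     # m/s^2, accelerometer sd for the gravity update
    lead_in_s: float = 1.0     # quiescent segment for the gravity-magnitude estimate


def _quat_mult(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q
    w2, x2, y2, z2 = r
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def _quat_from_rotvec(v: np.ndarray) -> np.ndarray:
    angle = float(np.linalg.norm(v))
    if angle < 1e-12:
        return np.array([1.0, 0.5 * v[0], 0.5 * v[1], 0.5 * v[2]]) / np.sqrt(
            1.0 + 0.25 * (v @ v)
        )
    axis = v / angle
    return np.concatenate(([np.cos(angle / 2.0)], np.sin(angle / 2.0) * axis))


def _quat_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], 0.0, v[0]]])


def _init_from_gravity(f_mean: np.ndarray) -> np.ndarray:
    """Quaternion aligning the measured gravity direction with world +z (yaw = 0)."""
    u = f_mean / np.linalg.norm(f_mean)  # body-frame unit vector toward world up
    z = np.array([0.0, 0.0, 1.0])
    # rotate u onto z: axis = u x z, angle between them
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    c = float(u @ z)
    if s < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0]) if c > 0 else np.array([0.0, 1.0, 0.0, 0.0])
    angle = np.arctan2(s, c)
    # world->body rotation of q maps body u to world z when q rotates by -angle about axis in body?
    # q maps body vectors to world: need R(q) u = z.
    rv = -axis / s * angle
    q = _quat_from_rotvec(rv)
    # _quat_from_rotvec builds body-frame increment; verify orientation sign
    if not np.allclose(_quat_to_matrix(q) @ u, z, atol=1e-8):
        q = _quat_from_rotvec(axis / s * angle)
    return q


def imu_horizontal_acceleration(
    imu: ImuSeries, config: AttitudeEkfConfig | None = None
) -> HeadAcceleration:
    """Estimate horizontal head acceleration from raw IMU channels.

    Attitude (roll/pitch) is tracked by a quaternion EKF that integrates the
    gyroscope and corrects toward the measured gravity direction; the
    specific force is then rotated into the stationary frame and gravity
    (estimated from the quiescent lead-in) is subtracted.  Raises if the
    accelerometer norm is inconsistent with gravity over the whole record.
    """
    cfg = config or AttitudeEkfConfig()
    t, acc, gyro = imu.t, imu.acc, imu.gyro
    fs = imu.fs
    dt = 1.0 / fs

    norms = np.linalg.norm(acc, axis=1)
    g_hat = float(np.mean(norms[: max(2, int(cfg.lead_in_s * fs))]))
    if np.median(np.abs(norms - g_hat)) > 0.5 * g_hat or g_hat < 1.0:
        raise ValueError(
            "accelerometer norm deviates >50% from gravity; attitude unreliable"
        )

    # initial attitude: de-rotate every accelerometer sample to the
    # first-sample body frame with the gyro, then average.  Sway keeps the
    # record-mean horizontal acceleration near zero, so the averaged
    # specific force points along gravity in the initial body frame even
    # though the subject moves (processing is offline, so using the whole
    # record is fair)
    q_rel = np.array([1.0, 0.0, 0.0, 0.0])
    f0 = np.zeros(3)
    for k in range(t.size):
        f0 += _quat_to_matrix(q_rel) @ acc[k]
        q_rel = _quat_mult(q_rel, _quat_from_rotvec(gyro[k] * dt))
        q_rel /= np.linalg.norm(q_rel)
    q = _init_from_gravity(f0 / t.size)
    # the quiescent lead-in pins the initial attitude, so P starts at the
    # steady state sqrt(Q*R) of the angle-error recursion; a larger P0 would
    # let horizontal accelerations tug the attitude for tens of seconds
    P = np.eye(3) * (cfg.sigma_gyro * dt) * (cfg.sigma_acc / g_hat)
    Q = np.eye(3) * (cfg.sigma_gyro * dt) ** 2
    R_meas = np.eye(3) * cfg.sigma_acc**2
    g_world = np.array([0.0, 0.0, g_hat])

    out = np.empty((t.size, 3))
    for k in range(t.size):
        if k > 0:
            dq = _quat_from_rotvec(gyro[k] * dt)
            q = _quat_mult(q, dq)
            q /= np.linalg.norm(q)
            Rb = _quat_to_matrix(dq)
            P = Rb.T @ P @ Rb + Q
        # gravity-direction update: h(dtheta) = (I - [dtheta]x) v, v = R^T g_world
        Rm = _quat_to_matrix(q)
        v = Rm.T @ g_world
        H = _skew(v)
        S = H @ P @ H.T + R_meas
        K = P @ H.T @ np.linalg.inv(S)
        innov = acc[k] - v
        dtheta = K @ innov
        q = _quat_mult(q, _quat_from_rotvec(dtheta))
        q /= np.linalg.norm(q)
        P = (np.eye(3) - K @ H) @ P
        # world-frame acceleration: a = R f + g_vec (g_vec = -g_hat z)
        out[k] = _quat_to_matrix(q) @ acc[k]
    out[:, 2] -= g_hat
    return HeadAcceleration(t=t, acc_x=out[:, 0], acc_y=out[:, 1])
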