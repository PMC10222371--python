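"""Time-series containers shared across the package.

All series are stored in SI units (m, m/s^2, N, N.m, rad, rad/s) on a single
uniform sampling grid.  Plane labels follow posturography convention:
``"ap"`` is anteroposterior (sagittal plane, forward = +x) and ``"ml"`` is
mediolateral (frontal plane, left = +y).  The horizontal displacement of the
body centre of mass (COM) is expressed in the moving, platform-fixed frame;
support-surface acceleration couples it to the stationary frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: maximum tolerated jitter of the sampling grid, seconds
_GRID_TOL = 1e-9

PLANES = ("ap", "ml")
METHODS = ("I", "II", "III", "IV")


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def check_uniform_grid(t: np.ndarray, tol: float = _GRID_TOL) -> float:
    """Validate a uniform time grid and return the sampling interval."""
    t = _as_array(t)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time grid must be a 1-D array with at least 2 samples")
    dt = np.diff(t)
    if np.any(~np.isfinite(dt)):
        raise ValueError("non-finite timestamps in time grid")
    dt0 = float(np.median(dt))
    # a dropped sample shows up as a gap > 1.5*dt; jitter beyond tol is rejected too
    gaps = np.nonzero(dt > 1.5 * dt0)[0]
    if gaps.size:
        raise ValueError(f"non-uniform timestamps: gap after row {int(gaps[0])}")
    bad = np.nonzero(np.abs(dt - dt0) > tol)[0]
    if bad.size:
        raise ValueError(
            f"non-uniform timestamps: deviation {np.max(np.abs(dt - dt0)):.3g} s "
            f"at row {int(bad[0])}"
        )
    return dt0


@dataclass
class ForcePlateSeries:
    """Force-platform channels: horizontal forces, moments and vertical force.

    ``R_x``/``R_y`` are the horizontal forces and ``N_x``/``N_y`` the moments
    about the plate axes, as measured by the platform (subject acting on the
    plate); ``F_z`` is the vertical load, positive downward onto the plate.
    """

    t: np.ndarray
    R_x: np.ndarray
    R_y: np.ndarray
    F_z: np.ndarray
    N_x: np.ndarray
    N_y: np.ndarray

    def __post_init__(self) -> None:
        self.t = _as_array(self.t)
        for name in ("R_x", "R_y", "F_z", "N_x", "N_y"):
            arr = _as_array(getattr(self, name))
            if arr.shape != self.t.shape:
                raise ValueError(f"channel {name} length {arr.size} != t length {self.t.size}")
            setattr(self, name, arr)
        check_uniform_grid(self.t)

    @property
    def fs(self) -> float:
        return 1.0 / check_uniform_grid(self.t)

    @property
    def n(self) -> int:
        return self.t.size


@dataclass
class ImuSeries:
    """Head-IMU raw channels: specific force and angular rate, body frame.

    The accelerometer reports specific force (it reads +g on the up axis at
    rest); the gyroscope reports angular rate about the body axes.
    """

    t: np.ndarray
    acc: np.ndarray   # (n, 3) m/s^2
    gyro: np.ndarray  # (n, 3) rad/s

    def __post_init__(self) -> None:
        self.t = _as_array(self.t)
        self.acc = _as_array(self.acc)
        self.gyro = _as_array(self.gyro)
        for name in ("acc", "gyro"):
            arr = getattr(self, name)
            if arr.shape != (self.t.size, 3):
                raise ValueError(f"{name} must have shape (n, 3)")
        check_uniform_grid(self.t)

    @property
    def fs(self) -> float:
        return 1.0 / check_uniform_grid(self.t)


@dataclass
class SupportMotion:
    """Horizontal support-surface acceleration in the stationary frame."""

    t: np.ndarray
    acc_x: np.ndarray                      # X''_s, m/s^2
    acc_y: np.ndarray                      # Y''_s, m/s^2
    disp_x: Optional[np.ndarray] = None    # X_s, m (optional)
    disp_y: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = _as_array(self.t)
        for name in ("acc_x", "acc_y"):
            arr = _as_array(getattr(self, name))
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        for name in ("disp_x", "disp_y"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, _as_array(val))
        check_uniform_grid(self.t)

    @classmethod
    def stationary(cls, t: np.ndarray) -> "SupportMotion":
        t = _as_array(t)
        z = np.zeros_like(t)
        return cls(t=t, acc_x=z.copy(), acc_y=z.copy(), disp_x=z.copy(), disp_y=z.copy())

    def acc(self, plane: str) -> np.ndarray:
        return self.acc_x if plane == "ap" else self.acc_y


@dataclass
class HeadAcceleration:
    """Horizontal head acceleration in the stationary frame."""

    t: np.ndarray
    acc_x: np.ndarray  # X''_h, m/s^2
    acc_y: np.ndarray  # Y''_h, m/s^2

    def __post_init__(self) -> None:
        self.t = _as_array(self.t)
        for name in ("acc_x", "acc_y"):
            arr = _as_array(getattr(self, name))
            if arr.shape != self.t.shape:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)

    def acc(self, plane: str) -> np.ndarray:
        return self.acc_x if plane == "ap" else self.acc_y

    def relative(self, support: SupportMotion, plane: str) -> np.ndarray:
        """Head acceleration relative to the support surface (moving frame)."""
        return self.acc(plane) - support.acc(plane)


@dataclass
class ComEstimate:
    """Per-plane COM estimate in the moving (platform) frame.

    ``disp`` is the horizontal COM displacement (m); ``vel`` is present only
    after Kalman fusion; ``acc`` is the COM acceleration.  ``acc_lower`` and
    ``acc_upper`` (lower/upper-body segment COM accelerations) are produced
    by the double-pendulum method only.
    """

    plane: str
    method: str
    t: np.ndarray
    disp: np.ndarray
    acc: Optional[np.ndarray] = None
    vel: Optional[np.ndarray] = None
    acc_lower: Optional[np.ndarray] = None
    acc_upper: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"plane must be one of {PLANES}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        self.t = _as_array(self.t)
        self.disp = _as_array(self.disp)
        if self.disp.shape != self.t.shape:
            raise ValueError("disp length mismatch")
        for name in ("acc", "vel", "acc_lower", "acc_upper"):
            val = getattr(self, name)
            if val is not None:
                arr = _as_array(val)
                if arr.shape != self.t.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)

    @property
    def fs(self) -> float:
        return 1.0 / check_uniform_grid(self.t)


@dataclass
class GroundTruth:
    """Simulator ground truth: joint angles and exact COM kinematics.

    ``theta_lower``/``theta_upper`` are the lower/upper segment tilt angles
    (sagittal: ankle/hip pendulum angles; frontal: leg/upper-body tilts).
    COM fields are filled in by the inverse-dynamics generators; they are in
    the moving frame, matching what the estimators reconstruct.
    """

    plane: str
    model: str                      # "single" | "double"
    t: np.ndarray
    theta_lower: np.ndarray
    theta_upper: np.ndarray
    theta_lower_d: np.ndarray
    theta_upper_d: np.ndarray
    theta_lower_dd: np.ndarray
    theta_upper_dd: np.ndarray
    support: SupportMotion
    com: Optional[np.ndarray] = None
    com_vel: Optional[np.ndarray] = None
    com_acc: Optional[np.ndarray] = None
    seg_lower: Optional[np.ndarray] = None
    seg_upper: Optional[np.ndarray] = None
    seg_lower_acc: Optional[np.ndarray] = None
    seg_upper_acc: Optional[np.ndarray] = None
    head_acc: Optional[np.ndarray] = None   # stationary-frame horizontal head acceleration

    @property
    def fs(self) -> float:
        return 1.0 / check_uniform_grid(self.t)


@dataclass
class TrialBundle:
    """One recorded (or simulated) trial: plate + optional head IMU + support."""

    plate: ForcePlateSeries
    support: SupportMotion
    imu: Optional[ImuSeries] = None
    head: Optional[HeadAcceleration] = None
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return self.plate.fs
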