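"""Algebraic COM estimators and the displacement/acceleration Kalman fusion.

Method I inverts the single-pendulum equations of motion sample by sample
using only force-platform channels; Method II adds the head acceleration
and inverts the double-pendulum (sagittal) or leg/pelvis/upper-body loop
(frontal) equations, yielding the body COM plus the lower- and upper-body
segment COM accelerations.  The Kalman filter then fuses the displacement
(observation) with the acceleration (input) into a causal displacement +
velocity estimate.

Sign conventions: +x forward, +y left, +z up, right-handed moments.  The
sagittal moment equation carries -N_y, the frontal one +N_x.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import linalg as sla

from .anthropometry import CompositeInertiaSet, SegmentParameterSet, SubjectDescriptor
from .series import (
    ComEstimate,
    ForcePlateSeries,
    HeadAcceleration,
    SupportMotion,
)

__all__ = [
    "estimate_method1",
    "estimate_method2",
    "method2_matrix",
    "build_kalman_matrices",
    "KalmanConfig",
    "KalmanState",
    "kalman_fuse",
]


def _check_lengths(*arrays: np.ndarray) -> int:
    n = arrays[0].size
    for a in arrays[1:]:
        if a.size != n:
            raise ValueError("series lengths do not match")
    return n


def estimate_method1(
    plane: str,
    plate: ForcePlateSeries,
    support: SupportMotion,
    params: SegmentParameterSet,
    inertias: CompositeInertiaSet,
    subject: SubjectDescriptor,
) -> ComEstimate:
    """Single-pendulum inversion (force platform only).

    Sagittal::

        x''_b = (-M X''_s - R_x) / m_b
        x_b   = [C_sag x''_b + M (L_f + l_b) X''_s + N_y] / (m_b g)

    Frontal uses R_y, -N_x and the constrained-loop inertia J_yb.
    """
    M, g = subject.mass, subject.g
    p = params
    if p.m_b * g == 0.0:
        raise ValueError("m_b * g must be nonzero")
    s_acc = support.acc(plane)
    _check_lengths(plate.t, s_acc)
    lever = M * (p.L_f + p.l_b)
    if plane == "ap":
        acc = (-M * s_acc - plate.R_x) / p.m_b
        disp = (inertias.C_sag * acc + lever * s_acc + plate.N_y) / (p.m_b * g)
    else:
        acc = (-M * s_acc - plate.R_y) / p.m_b
        disp = (inertias.J_yb * acc + lever * s_acc - plate.N_x) / (p.m_b * g)
    return ComEstimate(plane=plane, method="I", t=plate.t, disp=disp, acc=acc)


def method2_matrix(
    plane: str,
    params: SegmentParameterSet,
    inertias: CompositeInertiaSet,
    subject: SubjectDescriptor,
) -> np.ndarray:
    """The 3x3 coefficient matrix of the double-pendulum inversion.

    Rows: horizontal force balance, moment balance, head-kinematics
    constraint; unknowns (seg_lower_acc, seg_upper_acc, com_disp).
    """
    p = params
    g = subject.g
    if plane == "ap":
        return np.array(
            [
                [p.m_1, p.m_2, 0.0],
                [inertias.J_x1, inertias.J_x2, -p.m_b * g],
                [(p.l_2 - p.L_2) * p.L_1 / (p.l_1 * p.l_2), p.L_2 / p.l_2, 0.0],
            ]
        )
    return np.array(
        [
            [2.0 * p.m_l + p.m_p * p.L_l / p.l_l, p.m_u, 0.0],
            [inertias.J_y1, inertias.J_y2, -p.m_b * g],
            [(p.l_u - p.L_u) * p.L_l / (p.l_l * p.l_u), p.L_u / p.l_u, 0.0],
        ]
    )


def estimate_method2(
    plane: str,
    plate: ForcePlateSeries,
    head: HeadAcceleration,
    support: SupportMotion,
    params: SegmentParameterSet,
    inertias: CompositeInertiaSet,
    subject: SubjectDescriptor,
) -> ComEstimate:
    """Double-pendulum inversion (force platform + head IMU).

    Solves, per sample, the 3x3 system whose rows are the horizontal force
    balance, the moment balance about the plate origin and the head
    acceleration constraint, for (seg_lower_acc, seg_upper_acc, com_disp);
    the body COM acceleration is the mass-weighted segment combination.
    """
    M, g = subject.mass, subject.g
    p = params
    s_acc = support.acc(plane)
    h_rel = head.relative(support, plane)
    _check_lengths(plate.t, s_acc, h_rel)
    A = method2_matrix(plane, params, inertias, subject)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"double-pendulum matrix ill-conditioned (cond={cond:.3g}) for these parameters"
        )
    lever = M * (p.L_f + p.l_b)
    if plane == "ap":
        rhs = np.vstack(
            [
                -M * s_acc - plate.R_x,
                -lever * s_acc - plate.N_y,
                h_rel,
            ]
        )
        w_lower, w_upper = p.m_1 / p.m_b, p.m_2 / p.m_b
    else:
        rhs = np.vstack(
            [
                -M * s_acc - plate.R_y,
                -lever * s_acc + plate.N_x,
                h_rel,
            ]
        )
        w_lower = (2.0 * p.m_l * p.l_l + p.m_p * p.L_l) / (p.m_b * p.l_l)
        w_upper = p.m_u / p.m_b
    lu, piv = sla.lu_factor(A)
    sol = sla.lu_solve((lu, piv), rhs)
    acc_lower, acc_upper, disp = sol
    acc = w_lower * acc_lower + w_upper * acc_upper
    return ComEstimate(
        plane=plane,
        method="II",
        t=plate.t,
        disp=disp,
        acc=acc,
        acc_lower=acc_lower,
        acc_upper=acc_upper,
    )


# ---------------------------------------------------------------------------
# Kalman fusion of displacement + acceleration into displacement + velocity
# ---------------------------------------------------------------------------


def build_kalman_matrices(dt: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Constant-velocity state model driven by the acceleration input.

    Returns A = [[1, dt], [0, 1]], b = [dt^2/2, dt], c = [1, 0] for state
    (displacement, velocity), input u = acceleration, observation y =
    displacement.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    A = np.array([[1.0, dt], [0.0, 1.0]])
    b = np.array([dt * dt / 2.0, dt])
    c = np.array([1.0, 0.0])
    return A, b, c


@dataclass
class KalmanConfig:
    """Design parameters of the displacement/velocity Kalman filter.

    ``Q_w`` (process) and ``Q_v`` (observation) are expressed in the working
    length unit; the default working unit is millimetres, in which the
    defaults Q_w = diag(0.0025, 0.04), Q_v = 1 correspond to sensor-scale
    noise of 1 mm on the observed displacement.  SI inputs (m, m/s^2) are
    converted in and out transparently.
    """

    dt: float = 0.01
    Q_w: np.ndarray = field(default_factory=lambda: np.diag([0.0025, 0.04]))
    Q_v: float = 1.0
    unit: str = "mm"            # working length unit: "mm" or "m"
    x0: Optional[np.ndarray] = None   # working units; default (first sample, 0)
    P0: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.Q_w = np.asarray(self.Q_w, dtype=float)
        if self.Q_w.shape != (2, 2) or not np.allclose(self.Q_w, self.Q_w.T):
            raise ValueError("Q_w must be a symmetric 2x2 matrix")
        if np.any(np.linalg.eigvalsh(self.Q_w) < -1e-12):
            raise ValueError("Q_w must be positive semidefinite")
        if not self.Q_v > 0:
            raise ValueError("Q_v must be positive")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.unit not in ("mm", "m"):
            raise ValueError("unit must be 'mm' or 'm'")

    @property
    def scale(self) -> float:
        """Working-unit length per metre."""
        return 1000.0 if self.unit == "mm" else 1.0


@dataclass
class KalmanState:
    """Filter state after one step: estimate, covariance and gain."""

    x: np.ndarray
    P: np.ndarray
    G: np.ndarray


def kalman_fuse(
    displacement: np.ndarray,
    acceleration: np.ndarray,
    cfg: KalmanConfig,
    return_states: bool = False,
):
    """Fuse a displacement observation with an acceleration input.

    Runs the strictly causal predict/update recursion

        x-(k) = A x(k-1) + b u(k)            P-(k) = A P A^T + Q_w
        G(k)  = P-(k) c^T / (c P-(k) c^T + Q_v)
        x(k)  = x-(k) + G(k) (y(k) - c x-(k))
        P(k)  = (I - G(k) c) P-(k)

    and returns (displacement, velocity) in the input (SI) units.  Samples
    with non-finite input are flagged as NaN in the output while the
    recursion coasts on prediction alone.
    """
    y = np.asarray(displacement, dtype=float) * cfg.scale
    u = np.asarray(acceleration, dtype=float) * cfg.scale
    n = _check_lengths(y, u)
    A, b, c = build_kalman_matrices(cfg.dt)

    x = np.array([y[0] if np.isfinite(y[0]) else 0.0, 0.0]) if cfg.x0 is None else np.asarray(
        cfg.x0, dtype=float
    ).copy()
    P = (
        np.diag([cfg.Q_v, 100.0 * cfg.Q_w[1, 1]])
        if cfg.P0 is None
        else np.asarray(cfg.P0, dtype=float).copy()
    )
    out = np.empty((n, 2))
    states = [] if return_states else None
    G = np.zeros(2)
    for k in range(n):
        ok = np.isfinite(y[k]) and np.isfinite(u[k])
        xm = A @ x + b * (u[k] if ok else 0.0)
        Pm = A @ P @ A.T + cfg.Q_w
        if ok:
            s = float(c @ Pm @ c) + cfg.Q_v
            G = (Pm @ c) / s
            x = xm + G * (y[k] - c @ xm)
            P = (np.eye(2) - np.outer(G, c)) @ Pm
            P = 0.5 * (P + P.T)
        else:
            x, P = xm, Pm
        out[k] = x if ok else np.nan
        if return_states:
            states.append(KalmanState(x=x.copy(), P=P.copy(), G=G.copy()))
    disp = out[:, 0] / cfg.scale
    vel = out[:, 1] / cfg.scale
    if return_states:
        return disp, vel, states
    return disp, vel
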