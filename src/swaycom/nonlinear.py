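"""Exact nonlinear Newton-Euler oracle for the planar pendulum models.

The linear estimators and the linear inverse-dynamics generator share the
small-angle approximation; this module is the independent cross-check.
It derives, symbolically (sympy) and without linearisation, the reaction
force and moment that a rigid double pendulum (sagittal) or the
leg/translating-pelvis/upper-body loop (frontal) exerts on the platform,
together with the exact head-point acceleration and ideal head-IMU
channels (specific force including gravity, angular rate).

Derivation: segment COM positions are written in plate-relative planar
coordinates as trig functions of the prescribed joint angles;
accelerations follow by symbolic differentiation.  The measured force is
the negative of the total inertial force (momentum theorem) and the
measured moment is the negative of the moment of inertial-minus-gravity
forces about the plate origin, so the only modelling inputs are the
segment geometries -- a code path with nothing in common with the linear
equations.  The feet (mass M - m_b) translate rigidly with the plate at
half ankle height.

Vertical motion is *not* neglected here: F_z carries the exact inertial
ripple and the moment includes the product nonlinearities that the linear
model drops.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Tuple

import numpy as np
import sympy as sp

from .anthropometry import SegmentParameterSet, SubjectDescriptor
from .series import ForcePlateSeries, GroundTruth, ImuSeries, SupportMotion

__all__ = ["inverse_dynamics_nonlinear"]

_SAG_PARAMS = ("m_1", "J_1", "l_1", "L_1", "m_2", "J_2", "l_2", "L_2", "L_f", "m_b")
_FRONT_PARAMS = ("m_l", "J_l", "l_l", "L_l", "m_p", "l_p", "L_p",
                 "m_u", "J_u", "l_u", "L_u", "L_f", "m_b")


@lru_cache(maxsize=None)
def _derive(plane: str):
    """Symbolic derivation, cached per plane; returns a lambdified function."""
    t = sp.Symbol("t")
    th1f = sp.Function("theta1")(t)
    th2f = sp.Function("theta2")(t)
    th1, th2, w1, w2, a1, a2 = sp.symbols("th1 th2 w1 w2 al1 al2")
    sdd = sp.Symbol("sdd")   # support horizontal acceleration (stationary frame)
    g = sp.Symbol("g")
    M = sp.Symbol("M")

    if plane == "ap":
        pnames = _SAG_PARAMS
        m1, J1, l1, L1, m2, J2, l2, L2, Lf, mb = sp.symbols(" ".join(pnames))
        # plate-relative positions (horizontal, vertical) and rotation angles
        # about the plane normal (+y axis: tilt toward +x is +theta)
        segs = [
            (m1, J1, l1 * sp.sin(th1f), Lf + l1 * sp.cos(th1f), th1f),
            (m2, J2, L1 * sp.sin(th1f) + l2 * sp.sin(th2f),
             Lf + L1 * sp.cos(th1f) + l2 * sp.cos(th2f), th2f),
        ]
        head_h = L1 * sp.sin(th1f) + L2 * sp.sin(th2f)
        head_v = Lf + L1 * sp.cos(th1f) + L2 * sp.cos(th2f)
    else:
        pnames = _FRONT_PARAMS
        ml, Jl, ll, Ll, mp_, lp, Lp, mu, Ju, lu, Lu, Lf, mb = sp.symbols(" ".join(pnames))
        segs = [
            (2 * ml, 2 * Jl, ll * sp.sin(th1f), Lf + ll * sp.cos(th1f), th1f),
            (mp_, sp.Integer(0), Ll * sp.sin(th1f), Lf + Ll * sp.cos(th1f) + lp, None),
            (mu, Ju, Ll * sp.sin(th1f) + lu * sp.sin(th2f),
             Lf + Ll * sp.cos(th1f) + Lp + lu * sp.cos(th2f), th2f),
        ]
        head_h = Ll * sp.sin(th1f) + Lu * sp.sin(th2f)
        head_v = Lf + Ll * sp.cos(th1f) + Lp + Lu * sp.cos(th2f)

    mf = M - mb      # feet, rigid with the plate
    hf = Lf / 2      # feet COM height above the plate surface

    def ddt(expr, order=1):
        return sp.diff(expr, t, order)

    # momentum theorem: measured horizontal force = -(total inertial force)
    R = -(mf * sdd + sum(m * (ddt(x, 2) + sdd) for m, _J, x, _z, _a in segs))
    Fz = mf * g + sum(m * (g + ddt(z, 2)) for m, _J, _x, z, _a in segs)

    # moment of (inertial - gravity) wrenches about the plate origin;
    # the measured moment is its negative.  A tilt toward the positive
    # horizontal axis is a rotation about +y in the sagittal plane but
    # about -x in the frontal plane, which flips both the gyroscopic sign
    # and the lever pattern (hence the two assembly branches and the N_x
    # sign flip relative to N_y).
    if plane == "ap":
        C = mf * hf * sdd
    else:
        C = -mf * hf * sdd
    for m, J, x, z, ang in segs:
        axs = ddt(x, 2) + sdd    # stationary-frame horizontal acceleration
        azs = ddt(z, 2)
        rot = 0 if ang is None else ddt(ang, 2)
        if plane == "ap":
            C += J * rot + z * m * axs - x * m * (azs + g)
        else:
            C += -J * rot + x * m * (azs + g) - z * m * axs
    N = -C

    # exact moving-frame body-COM kinematics (feet excluded)
    com = sum(m * x for m, _J, x, _z, _a in segs) / mb
    com_upright = com.subs({th1f: 0, th2f: 0})
    com = com - com_upright   # displacement from upright (zero for these geometries)

    head_ah = ddt(head_h, 2) + sdd          # stationary frame, horizontal
    head_av = ddt(head_v, 2)

    # ideal IMU on the upper segment: specific force in the sensor frame
    sa = th2f
    if plane == "ap":
        f1 = sp.cos(sa) * head_ah - sp.sin(sa) * (head_av + g)   # body x
        f2 = sp.Integer(0)                                       # body y
        f3 = sp.sin(sa) * head_ah + sp.cos(sa) * (head_av + g)   # body z
        gyro_axis = 1    # rate about body y = +theta2_dot
    else:
        f1 = sp.Integer(0)
        f2 = sp.cos(sa) * head_ah - sp.sin(sa) * (head_av + g)
        f3 = sp.sin(sa) * head_ah + sp.cos(sa) * (head_av + g)
        gyro_axis = 0    # rate about body x = -theta2_dot

    outputs = [R, Fz, N, head_ah, head_av, com, ddt(com, 1), ddt(com, 2), f1, f2, f3]
    rep = [
        (ddt(th1f, 2), a1), (ddt(th2f, 2), a2),
        (ddt(th1f, 1), w1), (ddt(th2f, 1), w2),
        (th1f, th1), (th2f, th2),
    ]
    outputs = [expr.subs(rep) for expr in outputs]
    psyms = sp.symbols(" ".join(pnames))
    if isinstance(psyms, sp.Symbol):
        psyms = (psyms,)
    args = (th1, th2, w1, w2, a1, a2, sdd, g, M) + tuple(psyms)
    func = sp.lambdify(args, outputs, modules="numpy")
    return func, pnames, gyro_axis


def inverse_dynamics_nonlinear(
    truth: GroundTruth,
    params: SegmentParameterSet,
    subject: SubjectDescriptor,
) -> Tuple[ForcePlateSeries, ImuSeries, SupportMotion]:
    """Exact reaction wrench and ideal IMU channels for prescribed motion.

    Fills the ground-truth COM fields with the *exact* (trig) moving-frame
    COM kinematics and the exact stationary-frame head acceleration, then
    returns the plate series, ideal IMU series and the support motion.
    """
    plane = truth.plane
    func, pnames, gyro_axis = _derive(plane)
    pvals = [getattr(params, n) for n in pnames]
    s_acc = truth.support.acc(plane)
    vals = func(
        truth.theta_lower, truth.theta_upper,
        truth.theta_lower_d, truth.theta_upper_d,
        truth.theta_lower_dd, truth.theta_upper_dd,
        s_acc, subject.g, subject.mass, *pvals,
    )
    n = truth.t.size
    vals = [np.broadcast_to(np.asarray(v, dtype=float), (n,)).copy() for v in vals]
    R, Fz, N, head_ah, _head_av, com, com_vel, com_acc, f1, f2, f3 = vals

    t = truth.t
    zero = np.zeros(n)
    if plane == "ap":
        plate = ForcePlateSeries(t=t, R_x=R, R_y=zero.copy(), F_z=Fz, N_x=zero.copy(), N_y=N)
        gyro_rate = truth.theta_upper_d
    else:
        plate = ForcePlateSeries(t=t, R_x=zero.copy(), R_y=R, F_z=Fz, N_x=N, N_y=zero.copy())
        gyro_rate = -truth.theta_upper_d
    gyro = np.zeros((n, 3))
    gyro[:, gyro_axis] = gyro_rate
    imu = ImuSeries(t=t, acc=np.column_stack([f1, f2, f3]), gyro=gyro)

    truth.model = "nonlinear"
    truth.com, truth.com_vel, truth.com_acc = com, com_vel, com_acc
    truth.head_acc = head_ah
    return plate, imu, truth.support
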