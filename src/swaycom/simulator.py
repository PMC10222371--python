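"""Synthetic standing-balance trials with exact ground truth.

Generates prescribed joint-angle trajectories for six motion conditions
(quiet standing, voluntary ankle-strategy sway AP/ML, voluntary
hip-strategy sway AP, support-surface sway AP/ML), evaluates the linear
small-angle models forward (inverse dynamics) to produce force-platform
and head-acceleration channels with the true COM kinematics attached, and
injects seeded sensor noise.  The exact nonlinear Newton-Euler oracle
lives in :mod:`swaycom.nonlinear`.

All trajectory derivatives are analytic (harmonic sums and smooth
envelopes differentiated in closed form), so the generated ground truth
is internally consistent to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .anthropometry import (
    CompositeInertiaSet,
    SegmentParameterSet,
    SubjectDescriptor,
    composite_inertias,
)
from .series import (
    ForcePlateSeries,
    GroundTruth,
    HeadAcceleration,
    ImuSeries,
    SupportMotion,
    TrialBundle,
)

__all__ = [
    "MotionSpec",
    "NoiseSpec",
    "sway_waveform",
    "make_trajectories",
    "inverse_dynamics_linear",
    "add_noise",
    "simulate_trial",
    "MOTIONS",
]

MOTIONS = ("quiet", "ankle_AP", "ankle_ML", "hip_AP", "sway_AP", "sway_ML")

#: default excitation levels per motion: joint amplitudes in rad (peak),
#: support sway in m (RMS).  Chosen to land in the regimes the six
#: experimental conditions exhibit: quiet-standing COM of a few mm RMS,
#: voluntary sway of a few cm, hip strategy with small COM excursion but
#: large counter-phase segment accelerations.
_DEFAULT_AMPLITUDE = {
    "quiet": 0.003,     # rad RMS of the band-limited background
    "ankle_AP": 0.04,
    "ankle_ML": 0.04,
    "hip_AP": 0.025,
    "sway_AP": 0.02,    # m RMS support displacement
    "sway_ML": 0.02,
}
_DEFAULT_FREQUENCY = {"ankle_AP": 0.25, "ankle_ML": 0.25, "hip_AP": 1.0}

#: hip strategy: theta_upper = -HIP_RATIO * theta_lower.  The ratio is below
#: the perfect COM-cancellation value (~3.14 for these segment parameters)
#: so the true COM still moves a few millimetres while the segment
#: accelerations are an order of magnitude larger -- the hip-motion regime.
HIP_RATIO = 2.0

#: quiet-standing background added to voluntary motions, rad RMS
BACKGROUND_RMS = 0.003

#: independent upper-body background as a fraction of the common background:
#: real sway is not a perfect single pendulum even in quiet standing, so a
#: small uncorrelated hip component rides on the in-phase sway
BACKGROUND_UPPER_FRACTION = 2.0 / 3.0

_SWAY_F0 = 0.05   # Hz, first harmonic of the support excitation
_SWAY_DF = 0.05   # Hz, harmonic spacing
_SWAY_N = 20      # number of harmonics
_RAMP_S = 2.0     # envelope ramp duration


@dataclass(frozen=True)
class MotionSpec:
    """One synthetic trial condition.

    ``amplitude`` is the peak joint angle (rad) for voluntary motions, the
    RMS background angle (rad) for quiet standing and the RMS support
    displacement (m) for sway trials; ``None`` selects the per-motion
    default.  ``plane`` is inferred from the motion tag ("quiet" defaults
    to the sagittal plane).
    """

    motion: str
    amplitude: Optional[float] = None
    frequency: Optional[float] = None
    duration: float = 40.0
    fs: float = 100.0
    seed: int = 0
    plane: Optional[str] = None
    background_rms: float = BACKGROUND_RMS
    background_upper_fraction: float = BACKGROUND_UPPER_FRACTION
    hip_ratio: float = HIP_RATIO

    def __post_init__(self) -> None:
        if self.motion not in MOTIONS:
            raise ValueError(f"unknown motion {self.motion!r}; expected one of {MOTIONS}")
        n = self.duration * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration * fs must be integral")
        amp = self.resolved_amplitude
        if self.motion in ("ankle_AP", "ankle_ML", "hip_AP", "quiet") and amp > 0.05:
            raise ValueError(
                f"joint amplitude {amp} rad exceeds the small-angle domain (0.05 rad)"
            )

    @property
    def resolved_amplitude(self) -> float:
        return _DEFAULT_AMPLITUDE[self.motion] if self.amplitude is None else self.amplitude

    @property
    def resolved_frequency(self) -> float:
        return _DEFAULT_FREQUENCY.get(self.motion, 0.0) if self.frequency is None else self.frequency

    @property
    def resolved_plane(self) -> str:
        if self.plane is not None:
            return self.plane
        return "ml" if self.motion.endswith("ML") else "ap"

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


# ---------------------------------------------------------------------------
# analytic building blocks
# ---------------------------------------------------------------------------


def _harmonics(t, freqs, amps, phases):
    """Sum of sinusoids with analytic first and second derivatives."""
    w = 2.0 * np.pi * np.asarray(freqs)
    arg = np.outer(t, w) + np.asarray(phases)
    a = np.asarray(amps)
    s = np.sin(arg) @ a
    sd = np.cos(arg) @ (a * w)
    sdd = -np.sin(arg) @ (a * w * w)
    return s, sd, sdd


def _envelope(t: np.ndarray, duration: float, ramp: float = _RAMP_S):
    """Raised-cosine on/off envelope with analytic derivatives."""
    e = np.ones_like(t)
    ed = np.zeros_like(t)
    edd = np.zeros_like(t)
    k = np.pi / ramp
    head = t < ramp
    tail = t > duration - ramp
    th = t[head]
    e[head] = 0.5 * (1.0 - np.cos(k * th))
    ed[head] = 0.5 * k * np.sin(k * th)
    edd[head] = 0.5 * k * k * np.cos(k * th)
    tt = duration - t[tail]
    e[tail] = 0.5 * (1.0 - np.cos(k * tt))
    ed[tail] = -0.5 * k * np.sin(k * tt)
    edd[tail] = 0.5 * k * k * np.cos(k * tt)
    return e, ed, edd


def _windowed(t, duration, s, sd, sdd):
    e, ed, edd = _envelope(t, duration)
    return e * s, ed * s + e * sd, edd * s + 2.0 * ed * sd + e * sdd


def _background(t, duration, rms, seed):
    """Band-limited (0.05-1.0 Hz) seeded random-phase sway background."""
    rng = np.random.default_rng(seed)
    freqs = _SWAY_F0 + _SWAY_DF * np.arange(_SWAY_N)
    amps = 1.0 / (1.0 + (freqs / 0.3) ** 2)
    phases = rng.uniform(0.0, 2.0 * np.pi, _SWAY_N)
    if rms == 0.0:
        z = np.zeros_like(t)
        return z, z.copy(), z.copy()
    amps *= rms / np.sqrt(np.sum(amps**2) / 2.0)
    s, sd, sdd = _harmonics(t, freqs, amps, phases)
    return _windowed(t, duration, s, sd, sdd)


def sway_waveform(
    duration: float, fs: float, rms_amplitude: float, seed: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Support-surface excitation: 20 harmonics at 0.05-1.0 Hz.

    Equal-amplitude harmonics with seed-determined phases, scaled to the
    requested RMS displacement; returns (displacement, velocity,
    acceleration) with the derivatives taken analytically.
    """
    if fs <= 2.0:
        raise ValueError("fs must exceed 2 Hz to represent the 1 Hz harmonic")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    freqs = _SWAY_F0 + _SWAY_DF * np.arange(_SWAY_N)
    phases = rng.uniform(0.0, 2.0 * np.pi, _SWAY_N)
    if rms_amplitude == 0.0:
        z = np.zeros(n)
        return z, z.copy(), z.copy()
    amps = np.full(_SWAY_N, rms_amplitude * np.sqrt(2.0 / _SWAY_N))
    return _harmonics(t, freqs, amps, phases)


def make_trajectories(spec: MotionSpec) -> GroundTruth:
    """Prescribed joint-angle trajectories (and support motion) for a trial.

    Returns a :class:`GroundTruth` with the angle series and support motion
    populated; COM kinematics are filled in by the inverse-dynamics
    generators, which define the model ("single" or "double") the truth
    refers to.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    plane = spec.resolved_plane
    amp = spec.resolved_amplitude
    zero = np.zeros(n)

    support = SupportMotion.stationary(t)
    if spec.motion.startswith("sway"):
        disp, _vel, acc = sway_waveform(spec.duration, spec.fs, amp, spec.seed)
        if plane == "ap":
            support = SupportMotion(t=t, acc_x=acc, acc_y=zero.copy(), disp_x=disp, disp_y=zero.copy())
        else:
            support = SupportMotion(t=t, acc_x=zero.copy(), acc_y=acc, disp_x=zero.copy(), disp_y=disp)

    # quiet-standing background: a common (in-phase, ankle-type) component
    # plus a smaller independent upper-body component, seeded independently
    # of the support phases
    bg_rms = amp if spec.motion == "quiet" else spec.background_rms
    b, bd, bdd = _background(t, spec.duration, bg_rms, spec.seed + 1)
    u, ud, udd = _background(
        t, spec.duration, bg_rms * spec.background_upper_fraction, spec.seed + 2
    )

    if spec.motion in ("quiet", "sway_AP", "sway_ML"):
        th1, th1d, th1dd = b, bd, bdd
        th2, th2d, th2dd = b + u, bd + ud, bdd + udd
    elif spec.motion in ("ankle_AP", "ankle_ML"):
        f = spec.resolved_frequency
        s, sd, sdd = _harmonics(t, [f], [amp], [0.0])
        v, vd, vdd = _windowed(t, spec.duration, s, sd, sdd)
        th1, th1d, th1dd = v + b, vd + bd, vdd + bdd
        th2, th2d, th2dd = v + b + u, vd + bd + ud, vdd + bdd + udd
    elif spec.motion == "hip_AP":
        f = spec.resolved_frequency
        s, sd, sdd = _harmonics(t, [f], [amp], [0.0])
        v, vd, vdd = _windowed(t, spec.duration, s, sd, sdd)
        r = spec.hip_ratio
        th1, th1d, th1dd = v + b, vd + bd, vdd + bdd
        th2, th2d, th2dd = -r * v + b + u, -r * vd + bd + ud, -r * vdd + bdd + udd
    else:  # pragma: no cover - guarded by MotionSpec validation
        raise ValueError(f"unsupported motion {spec.motion!r}")

    return GroundTruth(
        plane=plane,
        model="double",
        t=t,
        theta_lower=th1,
        theta_upper=th2,
        theta_lower_d=th1d,
        theta_upper_d=th2d,
        theta_lower_dd=th1dd,
        theta_upper_dd=th2dd,
        support=support,
    )


# ---------------------------------------------------------------------------
# linear (small-angle) inverse dynamics
# ---------------------------------------------------------------------------


def inverse_dynamics_linear(
    truth: GroundTruth,
    params: SegmentParameterSet,
    subject: SubjectDescriptor,
    inertias: Optional[CompositeInertiaSet] = None,
    model: str = "double",
) -> Tuple[ForcePlateSeries, HeadAcceleration, SupportMotion]:
    """Evaluate the small-angle equations of motion forward.

    Substitutes the prescribed angle kinematics into the linear models to
    produce plate channels and the stationary-frame head acceleration, and
    fills the ground-truth COM fields (moving frame).  ``model`` selects
    which linear model defines the truth: the double pendulum / frontal
    loop ("double") or the constrained single pendulum ("single", which
    reads the lower angle as the common tilt).  F_z is constant M*g (the
    linear models neglect vertical motion).

    This generator is a deliberately separate code path from the
    estimators: the equations are written out forward here, so an
    estimator inverting them is a genuine round trip.
    """
    p = params
    iner = inertias if inertias is not None else composite_inertias(p)
    M, g = subject.mass, subject.g
    t = truth.t
    plane = truth.plane
    s_acc = truth.support.acc(plane)
    zero = np.zeros_like(t)
    lever = M * (p.L_f + p.l_b)

    th1, th2 = truth.theta_lower, truth.theta_upper
    th1dd, th2dd = truth.theta_lower_dd, truth.theta_upper_dd

    if model == "single":
        # constrained model: common tilt read from the lower angle
        com = p.l_b * th1
        com_vel = p.l_b * truth.theta_lower_d
        com_acc = p.l_b * th1dd
        if plane == "ap":
            R = -M * s_acc - p.m_b * com_acc
            N_y = -(iner.C_sag * com_acc - p.m_b * g * com + lever * s_acc)
            plate = ForcePlateSeries(t=t, R_x=R, R_y=zero.copy(), F_z=np.full_like(t, M * g),
                                     N_x=zero.copy(), N_y=N_y)
            head_rel = (p.L_1 + p.L_2) * th1dd
            head = HeadAcceleration(t=t, acc_x=head_rel + s_acc, acc_y=zero.copy())
            x1dd, x2dd = p.l_1 * th1dd, (p.L_1 + p.l_2) * th1dd
            x1, x2 = p.l_1 * th1, (p.L_1 + p.l_2) * th1
        else:
            R = -M * s_acc - p.m_b * com_acc
            N_x = iner.J_yb * com_acc - p.m_b * g * com + lever * s_acc
            plate = ForcePlateSeries(t=t, R_x=zero.copy(), R_y=R, F_z=np.full_like(t, M * g),
                                     N_x=N_x, N_y=zero.copy())
            head_rel = (p.L_l + p.L_u) * th1dd
            head = HeadAcceleration(t=t, acc_x=zero.copy(), acc_y=head_rel + s_acc)
            x1dd, x2dd = p.l_l * th1dd, (p.L_l + p.l_u) * th1dd
            x1, x2 = p.l_l * th1, (p.L_l + p.l_u) * th1
    elif model == "double":
        if plane == "ap":
            x1, x1d, x1dd = p.l_1 * th1, p.l_1 * truth.theta_lower_d, p.l_1 * th1dd
            x2 = p.L_1 * th1 + p.l_2 * th2
            x2d = p.L_1 * truth.theta_lower_d + p.l_2 * truth.theta_upper_d
            x2dd = p.L_1 * th1dd + p.l_2 * th2dd
            com = (p.m_1 * x1 + p.m_2 * x2) / p.m_b
            com_vel = (p.m_1 * x1d + p.m_2 * x2d) / p.m_b
            com_acc = (p.m_1 * x1dd + p.m_2 * x2dd) / p.m_b
            R = -M * s_acc - (p.m_1 * x1dd + p.m_2 * x2dd)
            N_y = -(iner.J_x1 * x1dd + iner.J_x2 * x2dd - p.m_b * g * com + lever * s_acc)
            plate = ForcePlateSeries(t=t, R_x=R, R_y=zero.copy(), F_z=np.full_like(t, M * g),
                                     N_x=zero.copy(), N_y=N_y)
            head_rel = (p.L_1 * (p.l_2 - p.L_2) / (p.l_1 * p.l_2)) * x1dd + (p.L_2 / p.l_2) * x2dd
            head = HeadAcceleration(t=t, acc_x=head_rel + s_acc, acc_y=zero.copy())
        else:
            w_l = 2.0 * p.m_l + p.m_p * p.L_l / p.l_l
            x1, x1d, x1dd = p.l_l * th1, p.l_l * truth.theta_lower_d, p.l_l * th1dd
            x2 = p.L_l * th1 + p.l_u * th2
            x2d = p.L_l * truth.theta_lower_d + p.l_u * truth.theta_upper_d
            x2dd = p.L_l * th1dd + p.l_u * th2dd
            com = (w_l * x1 + p.m_u * x2) / p.m_b
            com_vel = (w_l * x1d + p.m_u * x2d) / p.m_b
            com_acc = (w_l * x1dd + p.m_u * x2dd) / p.m_b
            R = -M * s_acc - (w_l * x1dd + p.m_u * x2dd)
            N_x = iner.J_y1 * x1dd + iner.J_y2 * x2dd - p.m_b * g * com + lever * s_acc
            plate = ForcePlateSeries(t=t, R_x=zero.copy(), R_y=R, F_z=np.full_like(t, M * g),
                                     N_x=N_x, N_y=zero.copy())
            head_rel = (p.L_l * (p.l_u - p.L_u) / (p.l_l * p.l_u)) * x1dd + (p.L_u / p.l_u) * x2dd
            head = HeadAcceleration(t=t, acc_x=zero.copy(), acc_y=head_rel + s_acc)
    else:
        raise ValueError("model must be 'single' or 'double'")

    truth.model = model
    truth.com, truth.com_vel, truth.com_acc = com, com_vel, com_acc
    truth.seg_lower, truth.seg_upper = x1, x2
    truth.seg_lower_acc, truth.seg_upper_acc = x1dd, x2dd
    truth.head_acc = head.acc(plane)
    return plate, head, truth.support


# ---------------------------------------------------------------------------
# sensor noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Per-channel white-noise levels, force drift and head-stream sync offset.

    All-zero (the default) is the identity.  ``sync_offset_s`` delays the
    head stream (IMU or head-acceleration channel) relative to the plate by
    the given time, interpolated on the common grid.
    """

    sd_force: float = 0.0        # N, on R_x/R_y
    sd_fz: float = 0.0           # N
    sd_moment: float = 0.0       # N.m, on N_x/N_y
    sd_support_acc: float = 0.0  # m/s^2
    sd_head_acc: float = 0.0     # m/s^2, on HeadAcceleration channels
    sd_imu_acc: float = 0.0      # m/s^2, on raw IMU specific force
    sd_imu_gyro: float = 0.0     # rad/s
    drift_force: float = 0.0     # N/s ramp added to R channels
    sync_offset_s: float = 0.0   # s, head stream delay
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("sd_force", "sd_fz", "sd_moment", "sd_support_acc",
                  "sd_head_acc", "sd_imu_acc", "sd_imu_gyro"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @classmethod
    def realistic(cls, seed: int = 0, **overrides) -> "NoiseSpec":
        """Sensor-grade defaults: strain-gauge plate and MEMS head IMU."""
        base = dict(
            sd_force=0.1,
            sd_fz=0.5,
            sd_moment=0.05,
            sd_support_acc=0.005,
            sd_head_acc=0.01,
            sd_imu_acc=0.01,
            sd_imu_gyro=0.002,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def _delayed(t: np.ndarray, x: np.ndarray, delay: float) -> np.ndarray:
    if delay == 0.0:
        return x.copy()
    return np.interp(t - delay, t, x)


def add_noise(
    spec: NoiseSpec,
    plate: Optional[ForcePlateSeries] = None,
    head: Optional[HeadAcceleration] = None,
    imu: Optional[ImuSeries] = None,
    support: Optional[SupportMotion] = None,
):
    """Corrupt simulated channels with seeded noise, drift and sync offset.

    Returns ``(plate, head, imu, support)`` copies in that order (None where
    the input was None); the draw order is fixed so a given seed produces
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    out_plate = out_head = out_imu = out_support = None
    if plate is not None:
        n = plate.n
        ramp = spec.drift_force * plate.t
        out_plate = ForcePlateSeries(
            t=plate.t.copy(),
            R_x=plate.R_x + rng.normal(0.0, spec.sd_force, n) + ramp,
            R_y=plate.R_y + rng.normal(0.0, spec.sd_force, n) + ramp,
            F_z=plate.F_z + rng.normal(0.0, spec.sd_fz, n),
            N_x=plate.N_x + rng.normal(0.0, spec.sd_moment, n),
            N_y=plate.N_y + rng.normal(0.0, spec.sd_moment, n),
        )
    if head is not None:
        n = head.t.size
        out_head = HeadAcceleration(
            t=head.t.copy(),
            acc_x=_delayed(head.t, head.acc_x, spec.sync_offset_s)
            + rng.normal(0.0, spec.sd_head_acc, n),
            acc_y=_delayed(head.t, head.acc_y, spec.sync_offset_s)
            + rng.normal(0.0, spec.sd_head_acc, n),
        )
    if imu is not None:
        n = imu.t.size
        acc = np.column_stack([_delayed(imu.t, imu.acc[:, i], spec.sync_offset_s) for i in range(3)])
        gyro = np.column_stack([_delayed(imu.t, imu.gyro[:, i], spec.sync_offset_s) for i in range(3)])
        out_imu = ImuSeries(
            t=imu.t.copy(),
            acc=acc + rng.normal(0.0, spec.sd_imu_acc, (n, 3)),
            gyro=gyro + rng.normal(0.0, spec.sd_imu_gyro, (n, 3)),
        )
    if support is not None:
        n = support.t.size
        out_support = SupportMotion(
            t=support.t.copy(),
            acc_x=support.acc_x + rng.normal(0.0, spec.sd_support_acc, n),
            acc_y=support.acc_y + rng.normal(0.0, spec.sd_support_acc, n),
            disp_x=None if support.disp_x is None else support.disp_x.copy(),
            disp_y=None if support.disp_y is None else support.disp_y.copy(),
        )
    return out_plate, out_head, out_imu, out_support


def simulate_trial(
    spec: MotionSpec,
    subject: SubjectDescriptor,
    model: str = "double",
    noise: Optional[NoiseSpec] = None,
) -> Tuple[TrialBundle, GroundTruth]:
    """Full synthetic trial: trajectories -> linear inverse dynamics -> noise."""
    from .anthropometry import derive_segment_parameters

    params = derive_segment_parameters(subject)
    truth = make_trajectories(spec)
    plate, head, support = inverse_dynamics_linear(truth, params, subject, model=model)
    if noise is not None:
        plate, head, _imu, support = add_noise(noise, plate=plate, head=head, support=support)
    bundle = TrialBundle(
        plate=plate,
        support=support,
        head=head,
        meta={
            "motion": spec.motion,
            "plane": truth.plane,
            "model": model,
            "fs": spec.fs,
            "seed": spec.seed,
            "subject_mass_kg": subject.mass,
            "subject_height_m": subject.height,
        },
    )
    return bundle, truth
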