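"""Baseline COM estimators from the prior posturography literature.

* Centre of pressure (COP) from plate moments and vertical load.
* Method III: the COP low-pass-filtering estimate of the COM (zero-phase
  Butterworth at a configurable cutoff; COP and COM coincide at DC and the
  COM attenuates COP content above the pendulum corner frequency).
* Method IV: double integration of the COM horizontal acceleration derived
  from the horizontal force, with zero-phase high-pass stabilisation after
  each integration to suppress drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .anthropometry import SegmentParameterSet, SubjectDescriptor
from .series import ComEstimate, ForcePlateSeries, SupportMotion
from .signal_processing import FILTER_ORDER, differentiate, zero_phase_butterworth

__all__ = ["CopSeries", "compute_cop", "estimate_method3", "estimate_method4"]

METHOD3_CUTOFF_HZ = 0.5
METHOD4_HIGHPASS_HZ = 0.1


@dataclass
class CopSeries:
    """Centre of pressure in the plate frame (m)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def component(self, plane: str) -> np.ndarray:
        return self.x if plane == "ap" else self.y


def compute_cop(plate: ForcePlateSeries, z_offset: float = 0.0) -> CopSeries:
    """COP from moments and vertical force.

        COP_x = (N_y - z0 R_x) / F_z        COP_y = -(N_x + z0 R_y) / F_z

    where ``z0`` is the height of the plate surface above the moment
    reference (default 0: origin on the surface).  Signs are chosen so that
    in static equilibrium the COP is the ground projection of the
    whole-body COM under the plate's moment conventions.
    """
    if np.any(plate.F_z <= 0):
        k = int(np.argmax(plate.F_z <= 0))
        raise ValueError(f"F_z must be positive everywhere (first violation at row {k})")
    x = (plate.N_y - z_offset * plate.R_x) / plate.F_z
    y = -(plate.N_x + z_offset * plate.R_y) / plate.F_z
    return CopSeries(t=plate.t, x=x, y=y)


def estimate_method3(
    cop: CopSeries,
    fs: float,
    plane: str = "ap",
    fc: float = METHOD3_CUTOFF_HZ,
    order: int = FILTER_ORDER,
) -> ComEstimate:
    """COP filtering method: COM displacement = zero-phase low-passed COP."""
    if fc >= fs / 2.0:
        raise ValueError("cutoff must be below the Nyquist frequency")
    disp = zero_phase_butterworth(cop.component(plane), fs, fc, order=order, mode="low")
    vel = differentiate(disp, fs)
    return ComEstimate(plane=plane, method="III", t=cop.t, disp=disp, vel=vel)


def estimate_method4(
    plate: ForcePlateSeries,
    support: SupportMotion,
    params: SegmentParameterSet,
    subject: SubjectDescriptor,
    plane: str = "ap",
    highpass_hz: float = METHOD4_HIGHPASS_HZ,
    order: int = FILTER_ORDER,
) -> ComEstimate:
    """Integration method: COM acceleration from the horizontal force,
    integrated twice with high-pass stabilisation after each integration.

    Integration constants are zero; the zero-phase high-pass bounds the
    double-integrated drift of force offsets.
    """
    M = subject.mass
    s_acc = support.acc(plane)
    R = plate.R_x if plane == "ap" else plate.R_y
    acc = (-M * s_acc - R) / params.m_b
    fs = plate.fs
    vel = cumulative_trapezoid(acc, dx=1.0 / fs, initial=0.0)
    vel = zero_phase_butterworth(vel, fs, highpass_hz, order=order, mode="high")
    disp = cumulative_trapezoid(vel, dx=1.0 / fs, initial=0.0)
    disp = zero_phase_butterworth(disp, fs, highpass_hz, order=order, mode="high")
    return ComEstimate(plane=plane, method="IV", t=plate.t, disp=disp, vel=vel, acc=acc)
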