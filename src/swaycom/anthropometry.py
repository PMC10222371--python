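"""Anthropometric scaling of the inverted-pendulum models.

Segment masses, COM heights, segment lengths and moments of inertia are
obtained from the subject's total mass ``M`` (kg) and height ``H`` (m) by
fixed regression coefficients (masses scale with M, lengths with H,
inertias with M*H^2).  Two planar models are parameterised:

* sagittal: single pendulum (whole body above the ankle) and double
  pendulum (lower body about the ankle + upper body about the hip);
* frontal: closed loop of two parallel legs, a translating pelvis and an
  upper body rotating about the waist; constraining the leg and upper-body
  tilts to be equal collapses it to a single pendulum.

The composite inertia coefficients assemble the moment equations into the
per-segment "moment per unit COM acceleration" form (units kg.m) used by
the estimators:

    J_x1 = J_1/l_1 + m_1 (L_f + l_1) - J_2 L_1 / (l_1 l_2)
    J_x2 = J_2/l_2 + m_2 (L_f + L_1 + l_2)
    J_y1 = 2 J_l/l_l - J_u L_l/(l_l l_u) + 2 m_l (L_f + l_l)
           + m_p (L_l/l_l)(L_f + L_l + l_p)
    J_y2 = J_u/l_u + m_u (L_f + L_l + L_p + l_u)
    J_yb = [2 J_l + J_u + 2 m_l l_l (L_f + l_l) + m_p L_l (L_f + L_l + l_p)
            + m_u (L_l + l_u)(L_f + L_l + L_p + l_u)] / l_b
    C_sag = J_b/l_b + m_b (L_f + l_b)

The pelvis translates without rotating, so its upper-body lever is
(L_l + l_u) while the lever *height* is (L_f + L_l + L_p + l_u); with the
tabulated coefficients J_y1*l_l + J_y2*(L_l + l_u) equals J_yb*l_b exactly.
The body moment of inertia J_b doubles as the sagittal single-pendulum
inertia (no separate value is tabulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

__all__ = [
    "SubjectDescriptor",
    "SegmentParameterSet",
    "CompositeInertiaSet",
    "derive_segment_parameters",
    "composite_inertias",
]

#: gravitational acceleration default, m/s^2
G_DEFAULT = 9.81

# regression coefficients: field -> (coefficient, scale) with scale in
# {"M", "H", "MH2"}.  Masses in kg, lengths in m, inertias in kg.m^2.
_COEFFS = {
    # sagittal plane
    "m_b": (0.978, "M"),
    "J_b": (0.0425, "MH2"),
    "l_b": (0.531, "H"),
    "m_1": (0.322, "M"),
    "J_1": (0.00223, "MH2"),
    "l_1": (0.285, "H"),
    "L_1": (0.460, "H"),
    "m_2": (0.656, "M"),
    "J_2": (0.0114, "MH2"),
    "l_2": (0.191, "H"),
    "L_2": (0.434, "H"),
    # frontal plane
    "m_l": (0.161, "M"),
    "J_l": (0.00524, "MH2"),
    "l_l": (0.285, "H"),
    "L_l": (0.460, "H"),
    "m_p": (0.187, "M"),
    "l_p": (0.056, "H"),
    "L_p": (0.144, "H"),
    "m_u": (0.469, "M"),
    "J_u": (0.00714, "MH2"),
    "l_u": (0.109, "H"),
    "L_u": (0.290, "H"),
    # foot (shared)
    "L_f": (0.038, "H"),
}


@dataclass(frozen=True)
class SubjectDescriptor:
    """Subject anthropometry: total mass (kg), height (m) and g (m/s^2)."""

    mass: float
    height: float
    g: float = G_DEFAULT

    def __post_init__(self) -> None:
        for name in ("mass", "height", "g"):
            val = getattr(self, name)
            if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
                raise ValueError(f"subject {name} must be finite and positive, got {val!r}")


@dataclass(frozen=True)
class SegmentParameterSet:
    """All per-segment parameters of the planar pendulum models (SI units).

    Sagittal: body (m_b, J_b, l_b), lower body (m_1, J_1, l_1, L_1), upper
    body (m_2, J_2, l_2, L_2).  Frontal: one leg (m_l, J_l, l_l, L_l),
    pelvis (m_p, l_p, L_p), upper body (m_u, J_u, l_u, L_u).  L_f is the
    ankle height.  Lowercase l is a COM offset within the segment; uppercase
    L is the full segment length (to the next joint, or to the head sensor
    for L_2/L_u).
    """

    m_b: float
    J_b: float
    l_b: float
    m_1: float
    J_1: float
    l_1: float
    L_1: float
    m_2: float
    J_2: float
    l_2: float
    L_2: float
    m_l: float
    J_l: float
    l_l: float
    L_l: float
    m_p: float
    l_p: float
    L_p: float
    m_u: float
    J_u: float
    l_u: float
    L_u: float
    L_f: float

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not math.isfinite(val):
                raise ValueError(f"segment parameter {f.name} must be finite, got {val!r}")
            if f.name.startswith(("m_", "J_")):
                if val < 0:
                    raise ValueError(f"segment parameter {f.name} must be >= 0, got {val!r}")
            elif val <= 0:   # lengths: strictly positive (they divide)
                raise ValueError(f"segment length {f.name} must be positive, got {val!r}")
        if not (self.L_1 > self.l_1 and self.L_l > self.l_l and self.L_u > self.l_u):
            raise ValueError("segment COM offsets must lie inside the segment (L > l)")


@dataclass(frozen=True)
class CompositeInertiaSet:
    """Composite moment coefficients (kg.m) of the planar moment equations."""

    J_x1: float
    J_x2: float
    J_y1: float
    J_y2: float
    J_yb: float
    C_sag: float


def derive_segment_parameters(subject: SubjectDescriptor) -> SegmentParameterSet:
    """Scale the regression table to a subject.

    Every field equals its tabulated coefficient times M, H or M*H^2.
    Mass closure is exact by construction: m_1 + m_2 == m_b and
    2*m_l + m_p + m_u == m_b (the printed coefficients sum exactly).
    """
    M, H = subject.mass, subject.height
    vals = {}
    for name, (coef, scale) in _COEFFS.items():
        if scale == "M":
            vals[name] = coef * M
        elif scale == "H":
            vals[name] = coef * H
        else:
            vals[name] = coef * M * H * H
    return SegmentParameterSet(**vals)


def composite_inertias(params: SegmentParameterSet) -> CompositeInertiaSet:
    """Assemble the composite inertia coefficients from segment parameters."""
    p = params
    for name in ("l_1", "l_2", "l_l", "l_u", "l_b"):
        if getattr(p, name) == 0.0:
            raise ValueError(f"zero-length {name} makes composite inertias singular")
    J_x1 = p.J_1 / p.l_1 + p.m_1 * (p.L_f + p.l_1) - p.J_2 * p.L_1 / (p.l_1 * p.l_2)
    J_x2 = p.J_2 / p.l_2 + p.m_2 * (p.L_f + p.L_1 + p.l_2)
    J_y1 = (
        2.0 * p.J_l / p.l_l
        - p.J_u * p.L_l / (p.l_l * p.l_u)
        + 2.0 * p.m_l * (p.L_f + p.l_l)
        + p.m_p * (p.L_l / p.l_l) * (p.L_f + p.L_l + p.l_p)
    )
    J_y2 = p.J_u / p.l_u + p.m_u * (p.L_f + p.L_l + p.L_p + p.l_u)
    J_yb = (
        2.0 * p.J_l
        + p.J_u
        + 2.0 * p.m_l * p.l_l * (p.L_f + p.l_l)
        + p.m_p * p.L_l * (p.L_f + p.L_l + p.l_p)
        + p.m_u * (p.L_l + p.l_u) * (p.L_f + p.L_l + p.L_p + p.l_u)
    ) / p.l_b
    C_sag = p.J_b / p.l_b + p.m_b * (p.L_f + p.l_b)
    return CompositeInertiaSet(J_x1=J_x1, J_x2=J_x2, J_y1=J_y1, J_y2=J_y2, J_yb=J_yb, C_sag=C_sag)
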