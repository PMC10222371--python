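"""Pipeline configuration: filters, Kalman design, baseline cutoffs.

Loadable from YAML with dotted keys mirroring the section names, e.g.::

    subject: {mass_kg: 70.0, height_m: 1.75}
    constants: {g: 9.81}
    filter: {highpass_hz: 0.1, order: 8, enabled: true}
    kalman: {q_disp: 0.0025, q_vel: 0.04, q_obs: 1.0, unit: mm}
    method3: {cutoff_hz: 0.5}
    method4: {highpass_hz: 0.1}
    cop: {z_offset_m: 0.0}
    validity: {cp_threshold: 0.8}
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .anthropometry import G_DEFAULT, SubjectDescriptor
from .estimators import KalmanConfig

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # force conditioning (zero-phase high-pass on R_x/R_y)
    filter_highpass_hz: float = 0.1
    filter_order: int = 8
    filter_enabled: bool = True
    reference_lowpass_hz: float = 3.0
    # Kalman design (working unit mm)
    kalman_q_disp: float = 0.0025
    kalman_q_vel: float = 0.04
    kalman_q_obs: float = 1.0
    kalman_unit: str = "mm"
    kalman_enabled: bool = True
    # baselines
    method3_cutoff_hz: float = 0.5
    method4_highpass_hz: float = 0.1
    cop_z_offset_m: float = 0.0
    # validity gate
    cp_threshold: float = 0.8

    def kalman(self, dt: float) -> KalmanConfig:
        return KalmanConfig(
            dt=dt,
            Q_w=np.diag([self.kalman_q_disp, self.kalman_q_vel]),
            Q_v=self.kalman_q_obs,
            unit=self.kalman_unit,
        )

    def as_dict(self) -> dict:
        return asdict(self)


_SECTION_MAP = {
    ("filter", "highpass_hz"): "filter_highpass_hz",
    ("filter", "order"): "filter_order",
    ("filter", "enabled"): "filter_enabled",
    ("filter", "reference_lowpass_hz"): "reference_lowpass_hz",
    ("kalman", "q_disp"): "kalman_q_disp",
    ("kalman", "q_vel"): "kalman_q_vel",
    ("kalman", "q_obs"): "kalman_q_obs",
    ("kalman", "unit"): "kalman_unit",
    ("kalman", "enabled"): "kalman_enabled",
    ("method3", "cutoff_hz"): "method3_cutoff_hz",
    ("method4", "highpass_hz"): "method4_highpass_hz",
    ("cop", "z_offset_m"): "cop_z_offset_m",
    ("validity", "cp_threshold"): "cp_threshold",
}


def load_config(path: str | Path) -> tuple[PipelineConfig, SubjectDescriptor | None]:
    """Read a YAML config; returns the pipeline config and, if the file
    declares a subject section, the subject descriptor."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    for (section, key), attr in _SECTION_MAP.items():
        if section in raw and key in raw[section]:
            setattr(cfg, attr, raw[section][key])
    subject = None
    if "subject" in raw:
        sub = raw["subject"]
        g = raw.get("constants", {}).get("g", G_DEFAULT)
        subject = SubjectDescriptor(mass=sub["mass_kg"], height=sub["height_m"], g=g)
    return cfg, subject
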