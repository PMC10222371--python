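"""Accuracy metrics and the single-pendulum applicability judgment.

RMSE and Pearson correlation are computed over a fixed evaluation window
(default 5-35 s, half-open, so the default yields exactly 3000 samples at
100 Hz).  The applicability gate C_p is the correlation between the COP
and the single-pendulum (Method I) COM estimate: when the body moves as
one pendulum the two track each other tightly, while hip-strategy motion
breaks the relationship, so a low C_p flags that Method I is invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .baselines import CopSeries
from .series import ComEstimate

__all__ = [
    "WINDOW_START_S",
    "WINDOW_END_S",
    "CP_THRESHOLD",
    "window_slice",
    "rmse_windowed",
    "pearson_cc",
    "cp_validity",
    "MetricReport",
    "evaluate_estimate",
]

WINDOW_START_S = 5.0
WINDOW_END_S = 35.0
CP_THRESHOLD = 0.8


def window_slice(n: int, fs: float, t0: float, t1: float) -> slice:
    """Samples with t0 <= k/fs < t1 (time measured from the first sample)."""
    k0 = int(np.ceil(t0 * fs - 1e-9))
    k1 = int(np.ceil(t1 * fs - 1e-9))
    if k0 < 0 or k1 > n or k0 >= k1:
        raise ValueError(f"evaluation window [{t0}, {t1}) s outside record of {n} samples")
    return slice(k0, k1)


def rmse_windowed(
    estimate: np.ndarray,
    truth: np.ndarray,
    fs: float,
    t0: float = WINDOW_START_S,
    t1: float = WINDOW_END_S,
) -> float:
    """Root-mean-square difference over the evaluation window."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("series must share one grid")
    w = window_slice(estimate.size, fs, t0, t1)
    d = estimate[w] - truth[w]
    return float(np.sqrt(np.mean(d * d)))


def pearson_cc(
    estimate: np.ndarray,
    truth: np.ndarray,
    fs: float,
    t0: float = WINDOW_START_S,
    t1: float = WINDOW_END_S,
) -> float:
    """Pearson correlation over the evaluation window.

    Raises on zero variance rather than silently returning 0.
    """
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("series must share one grid")
    w = window_slice(estimate.size, fs, t0, t1)
    a = estimate[w] - np.mean(estimate[w])
    b = truth[w] - np.mean(truth[w])
    va, vb = float(a @ a), float(b @ b)
    if va == 0.0 or vb == 0.0:
        raise ValueError("correlation undefined: zero variance in the window")
    return float(a @ b / np.sqrt(va * vb))


def cp_validity(
    cop: CopSeries,
    com_method1: ComEstimate,
    fs: Optional[float] = None,
    threshold: float = CP_THRESHOLD,
    t0: float = WINDOW_START_S,
    t1: float = WINDOW_END_S,
) -> Tuple[float, bool]:
    """COP / Method-I-COM correlation and the validity verdict (C_p > threshold)."""
    if com_method1.method != "I":
        raise ValueError("cp_validity judges the single-pendulum (Method I) estimate")
    fs = com_method1.fs if fs is None else fs
    cp = pearson_cc(cop.component(com_method1.plane), com_method1.disp, fs, t0, t1)
    return cp, bool(cp > threshold)


@dataclass
class MetricReport:
    """Windowed accuracy metrics for one estimate against ground truth.

    ``rmse`` and ``cc`` are keyed by quantity (``disp``, ``vel``, ``acc``,
    ``acc_lower``, ``acc_upper``); units are SI (m, m/s, m/s^2).
    """

    plane: str
    method: str
    window: Tuple[float, float]
    n_samples: int
    rmse: Dict[str, float] = field(default_factory=dict)
    cc: Dict[str, float] = field(default_factory=dict)
    cp: Optional[float] = None
    valid_method1: Optional[bool] = None

    def as_dict(self) -> dict:
        out = {
            "plane": self.plane,
            "method": self.method,
            "window_s": list(self.window),
            "n_samples": self.n_samples,
        }
        for q, v in self.rmse.items():
            out[f"rmse_{q}"] = v
        for q, v in self.cc.items():
            out[f"cc_{q}"] = v
        if self.cp is not None:
            out["cp"] = self.cp
            out["valid_method1"] = self.valid_method1
        return out


def evaluate_estimate(
    est: ComEstimate,
    truth_fields: Dict[str, np.ndarray],
    fs: Optional[float] = None,
    t0: float = WINDOW_START_S,
    t1: float = WINDOW_END_S,
    cop: Optional[CopSeries] = None,
    com_method1: Optional[ComEstimate] = None,
    threshold: float = CP_THRESHOLD,
) -> MetricReport:
    """Windowed RMSE/C_C per available quantity, plus optionally C_p.

    ``truth_fields`` maps quantity names to ground-truth series; only
    quantities present in both the estimate and the truth are scored.
    """
    fs = est.fs if fs is None else fs
    w = window_slice(est.t.size, fs, t0, t1)
    report = MetricReport(
        plane=est.plane, method=est.method, window=(t0, t1), n_samples=w.stop - w.start
    )
    pairs = {
        "disp": est.disp,
        "vel": est.vel,
        "acc": est.acc,
        "acc_lower": est.acc_lower,
        "acc_upper": est.acc_upper,
    }
    for q, series in pairs.items():
        ref = truth_fields.get(q)
        if series is None or ref is None:
            continue
        report.rmse[q] = rmse_windowed(series, ref, fs, t0, t1)
        report.cc[q] = pearson_cc(series, ref, fs, t0, t1)
    if cop is not None and com_method1 is not None:
        report.cp, report.valid_method1 = cp_validity(
            cop, com_method1, fs, threshold=threshold, t0=t0, t1=t1
        )
    return report
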