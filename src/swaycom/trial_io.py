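"""CSV schemas and readers/writers for trials, estimates and ground truth.

Dialect: comma-separated, UTF-8, '.' decimal, one header row of
``name[unit]`` labels, time in seconds from trial start.  Sensor files are
SI; estimate/truth files use the clinical reporting units (mm, mm/s,
mm/s^2).  Writing is deterministic (fixed column order and number
formatting), so identical inputs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .series import (
    ComEstimate,
    ForcePlateSeries,
    GroundTruth,
    HeadAcceleration,
    ImuSeries,
    SupportMotion,
    TrialBundle,
)

__all__ = [
    "write_trial",
    "read_trial",
    "write_estimates",
    "read_estimates",
    "write_truth",
    "read_truth",
]

_FLOAT_FMT = "%.17g"

PLATE_COLUMNS = ["t[s]", "Rx[N]", "Ry[N]", "Fz[N]", "Nx[Nm]", "Ny[Nm]"]
IMU_COLUMNS = ["t[s]", "ax[m/s2]", "ay[m/s2]", "az[m/s2]", "gx[rad/s]", "gy[rad/s]", "gz[rad/s]"]
SUPPORT_COLUMNS = ["t[s]", "Xsdd[m/s2]", "Ysdd[m/s2]"]
SUPPORT_OPTIONAL = ["Xs[m]", "Ys[m]"]
HEAD_COLUMNS = ["t[s]", "Xhdd[m/s2]", "Yhdd[m/s2]"]
ESTIMATE_COLUMNS = ["t[s]", "xb[mm]", "vb[mm/s]", "ab[mm/s2]", "a1[mm/s2]", "a2[mm/s2]"]


def _write_csv(path: Path, data: dict) -> None:
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def _read_csv(path: Path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    # round_trip parsing: the default fast parser can be 1 ulp off, which
    # would break the written-value == read-value contract
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path.name}: missing column {col.split('[')[0]!r} ({col})")
    return df


def write_trial(bundle: TrialBundle, directory: str | Path, prefix: str = "trial") -> dict:
    """Write plate/support (+ head and/or IMU) CSVs and a metadata YAML."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = bundle.plate
    paths["plate"] = d / f"{prefix}_plate.csv"
    _write_csv(paths["plate"], dict(zip(PLATE_COLUMNS, [p.t, p.R_x, p.R_y, p.F_z, p.N_x, p.N_y])))
    s = bundle.support
    cols = dict(zip(SUPPORT_COLUMNS, [s.t, s.acc_x, s.acc_y]))
    if s.disp_x is not None and s.disp_y is not None:
        cols["Xs[m]"], cols["Ys[m]"] = s.disp_x, s.disp_y
    paths["support"] = d / f"{prefix}_support.csv"
    _write_csv(paths["support"], cols)
    if bundle.head is not None:
        h = bundle.head
        paths["head"] = d / f"{prefix}_head.csv"
        _write_csv(paths["head"], dict(zip(HEAD_COLUMNS, [h.t, h.acc_x, h.acc_y])))
    if bundle.imu is not None:
        m = bundle.imu
        paths["imu"] = d / f"{prefix}_imu.csv"
        _write_csv(
            paths["imu"],
            dict(zip(IMU_COLUMNS, [m.t, m.acc[:, 0], m.acc[:, 1], m.acc[:, 2],
                                   m.gyro[:, 0], m.gyro[:, 1], m.gyro[:, 2]])),
        )
    paths["meta"] = d / f"{prefix}_meta.yaml"
    paths["meta"].write_text(yaml.safe_dump(bundle.meta, sort_keys=True))
    return paths


def read_trial(directory: str | Path, prefix: str = "trial") -> TrialBundle:
    """Read a trial written by :func:`write_trial` (head/IMU optional)."""
    d = Path(directory)
    plate_df = _read_csv(d / f"{prefix}_plate.csv", PLATE_COLUMNS)
    plate = ForcePlateSeries(
        t=plate_df["t[s]"].to_numpy(),
        R_x=plate_df["Rx[N]"].to_numpy(),
        R_y=plate_df["Ry[N]"].to_numpy(),
        F_z=plate_df["Fz[N]"].to_numpy(),
        N_x=plate_df["Nx[Nm]"].to_numpy(),
        N_y=plate_df["Ny[Nm]"].to_numpy(),
    )
    sup_df = _read_csv(d / f"{prefix}_support.csv", SUPPORT_COLUMNS)
    support = SupportMotion(
        t=sup_df["t[s]"].to_numpy(),
        acc_x=sup_df["Xsdd[m/s2]"].to_numpy(),
        acc_y=sup_df["Ysdd[m/s2]"].to_numpy(),
        disp_x=sup_df["Xs[m]"].to_numpy() if "Xs[m]" in sup_df else None,
        disp_y=sup_df["Ys[m]"].to_numpy() if "Ys[m]" in sup_df else None,
    )
    head = None
    if (d / f"{prefix}_head.csv").exists():
        h_df = _read_csv(d / f"{prefix}_head.csv", HEAD_COLUMNS)
        head = HeadAcceleration(
            t=h_df["t[s]"].to_numpy(),
            acc_x=h_df["Xhdd[m/s2]"].to_numpy(),
            acc_y=h_df["Yhdd[m/s2]"].to_numpy(),
        )
    imu = None
    if (d / f"{prefix}_imu.csv").exists():
        m_df = _read_csv(d / f"{prefix}_imu.csv", IMU_COLUMNS)
        imu = ImuSeries(
            t=m_df["t[s]"].to_numpy(),
            acc=m_df[["ax[m/s2]", "ay[m/s2]", "az[m/s2]"]].to_numpy(),
            gyro=m_df[["gx[rad/s]", "gy[rad/s]", "gz[rad/s]"]].to_numpy(),
        )
    meta = {}
    meta_path = d / f"{prefix}_meta.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
    return TrialBundle(plate=plate, support=support, head=head, imu=imu, meta=meta)


def _mm(x: Optional[np.ndarray], n: int) -> np.ndarray:
    if x is None:
        return np.full(n, np.nan)
    return np.asarray(x, dtype=float) * 1e3


def write_estimates(est: ComEstimate, path: str | Path, metrics: Optional[dict] = None) -> Path:
    """Write an estimate CSV (mm units); optionally a metrics sidecar YAML.

    An empty estimate yields a header-only file.
    """
    path = Path(path)
    n = est.t.size
    _write_csv(
        path,
        dict(zip(ESTIMATE_COLUMNS,
                 [est.t, _mm(est.disp, n), _mm(est.vel, n), _mm(est.acc, n),
                  _mm(est.acc_lower, n), _mm(est.acc_upper, n)])),
    )
    if metrics is not None:
        sidecar = path.with_suffix(".metrics.yaml")
        sidecar.write_text(yaml.safe_dump(metrics, sort_keys=True))
    return path


def read_estimates(path: str | Path, plane: str = "ap", method: str = "II") -> ComEstimate:
    df = _read_csv(Path(path), ESTIMATE_COLUMNS)

    def col(name):
        v = df[name].to_numpy() / 1e3
        return None if np.all(np.isnan(v)) else v

    return ComEstimate(
        plane=plane,
        method=method,
        t=df["t[s]"].to_numpy(),
        disp=df["xb[mm]"].to_numpy() / 1e3,
        vel=col("vb[mm/s]"),
        acc=col("ab[mm/s2]"),
        acc_lower=col("a1[mm/s2]"),
        acc_upper=col("a2[mm/s2]"),
    )


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Ground-truth CSV mirroring the estimate schema (mm units)."""
    path = Path(path)
    n = truth.t.size
    _write_csv(
        path,
        dict(zip(ESTIMATE_COLUMNS,
                 [truth.t, _mm(truth.com, n), _mm(truth.com_vel, n), _mm(truth.com_acc, n),
                  _mm(truth.seg_lower_acc, n), _mm(truth.seg_upper_acc, n)])),
    )
    return path


def read_truth(path: str | Path) -> dict:
    """Read a truth CSV into the quantity->series mapping used for scoring."""
    df = _read_csv(Path(path), ESTIMATE_COLUMNS)
    out = {"t": df["t[s]"].to_numpy()}
    for key, col in [("disp", "xb[mm]"), ("vel", "vb[mm/s]"), ("acc", "ab[mm/s2]"),
                     ("acc_lower", "a1[mm/s2]"), ("acc_upper", "a2[mm/s2]")]:
        v = df[col].to_numpy() / 1e3
        if not np.all(np.isnan(v)):
            out[key] = v
    return out
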