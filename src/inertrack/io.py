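"""CSV I/O for IMU data and pose trajectories.

Dialects (all angles in radians, timestamps in seconds, lossless float
round trip):

* IMU CSV columns: ``t, imu_id, gyr_x..z [rad/s], acc_x..z [m/s^2]`` and
  optionally ``mag_x..z`` (unitless);
* trajectory CSV columns: ``t, frame_id, qw, qx, qy, qz, px, py, pz [m]``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .results import TrackingResult
from .simulate import IMUDataset, MotionTrajectory

__all__ = [
    "read_imu_csv",
    "write_imu_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "trajectory_frames",
    "result_to_trajectory_frame",
]

_IMU_COLS = ["t", "imu_id", "gyr_x", "gyr_y", "gyr_z", "acc_x", "acc_y", "acc_z"]
_MAG_COLS = ["mag_x", "mag_y", "mag_z"]
_TRAJ_COLS = ["t", "frame_id", "qw", "qx", "qy", "qz", "px", "py", "pz"]


def write_imu_csv(data: IMUDataset, path) -> None:
    frames = []
    for i in range(data.n_imus):
        df = pd.DataFrame(
            {
                "t": data.t,
                "imu_id": i,
                "gyr_x": data.gyr[i, :, 0], "gyr_y": data.gyr[i, :, 1], "gyr_z": data.gyr[i, :, 2],
                "acc_x": data.acc[i, :, 0], "acc_y": data.acc[i, :, 1], "acc_z": data.acc[i, :, 2],
            }
        )
        if data.mag is not None:
            df["mag_x"], df["mag_y"], df["mag_z"] = (data.mag[i, :, k] for k in range(3))
        frames.append(df)
    pd.concat(frames).to_csv(path, index=False)


def read_imu_csv(path) -> IMUDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _IMU_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    has_mag = all(c in df.columns for c in _MAG_COLS)
    imu_ids = sorted(df.imu_id.unique())
    per = []
    for i in imu_ids:
        sub = df[df.imu_id == i].sort_index()
        t = sub.t.to_numpy()
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(f"{path}: non-monotone timestamps for imu {i} near row {bad}")
        per.append(sub)
    t0 = per[0].t.to_numpy()
    for i, sub in zip(imu_ids, per):
        if len(sub) != len(t0) or not np.allclose(sub.t.to_numpy(), t0):
            raise ValueError(f"{path}: imu {i} timestamps differ from imu {imu_ids[0]}")
    n = len(t0)
    gyr = np.stack([sub[["gyr_x", "gyr_y", "gyr_z"]].to_numpy() for sub in per])
    acc = np.stack([sub[["acc_x", "acc_y", "acc_z"]].to_numpy() for sub in per])
    mag = np.stack([sub[_MAG_COLS].to_numpy() for sub in per]) if has_mag else None
    T = float(np.median(np.diff(t0))) if n > 1 else 0.01
    return IMUDataset(t0, gyr, acc, mag, T)


def trajectory_frames(traj: MotionTrajectory, which: str = "segment"):
    """Iterate ``(frame_id, quat (n_t,4), pos (n_t,3))`` of a trajectory."""
    q = traj.seg_quat if which == "segment" else traj.imu_quat
    p = traj.seg_pos if which == "segment" else traj.imu_pos
    for i in range(q.shape[0]):
        yield i, q[i], p[i]


def write_trajectory_csv(t: np.ndarray, frames, path) -> None:
    """``frames``: iterable of ``(frame_id, quat (n_t,4), pos (n_t,3))``."""
    rows = []
    for fid, q, p in frames:
        rows.append(
            pd.DataFrame(
                {
                    "t": t, "frame_id": fid,
                    "qw": q[:, 0], "qx": q[:, 1], "qy": q[:, 2], "qz": q[:, 3],
                    "px": p[:, 0], "py": p[:, 1], "pz": p[:, 2],
                }
            )
        )
    pd.concat(rows).to_csv(path, index=False)


def result_to_trajectory_frame(res: TrackingResult):
    return [(i, res.seg_quat[i], res.seg_pos[i]) for i in range(res.n_segments)]


def read_trajectory_csv(path):
    """Returns ``(t, quat (n_frames, n_t, 4), pos (n_frames, n_t, 3))``.

    Quaternions are renormalized on read; drift beyond 1e-6 triggers a
    warning (the file was probably not written by this package).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRAJ_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    ids = sorted(df.frame_id.unique())
    qs, ps = [], []
    t = None
    for i in ids:
        sub = df[df.frame_id == i]
        t = sub.t.to_numpy()
        q = sub[["qw", "qx", "qy", "qz"]].to_numpy()
        n = np.linalg.norm(q, axis=1)
        if np.any(np.abs(n - 1.0) > 1e-6):
            warnings.warn(
                f"{path}: quaternion norms deviate up to {np.abs(n - 1).max():.2e}; renormalizing"
            )
        qs.append(q / n[:, None])
        ps.append(sub[["px", "py", "pz"]].to_numpy())
    return t, np.stack(qs), np.stack(ps)
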