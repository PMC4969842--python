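"""Synthetic motion and IMU data generation for the three-segment arm study.

The study sequence drives every rotational DoF of the chain with the same
analytic excitation ``phi(beta) = sin(beta/2) * sin(beta) * pi`` sampled over
one ``2*pi`` period in 629 steps of 10 ms.  This covers a ±139 deg range of
motion per DoF with smoothly varying, periodically accelerating and
direction-changing angular velocities, while the chain root stays pinned.

IMU data is obtained the way a strapdown sensor would see it: body-frame
angular velocity from differentiated orientations, specific force from the
second derivative of the IMU position minus gravity, rotated into the IMU
frame, and an (optional) artificial magnetometer that measures the global
x-axis in the IMU frame.  Calibration-error injection perturbs the model
used for *generating* the data, never the ground-truth segment poses that
trackers are scored against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .body import BodyModel, build_arm_model, chain_fk_matrices
from .quat import matrix_to_quat, qconj, qexp, qlog, qmul, qnormalize, qrotate

__all__ = [
    "GRAVITY",
    "AngleSequenceParams",
    "MotionTrajectory",
    "IMUDataset",
    "NoiseConfig",
    "CalibrationErrorSpec",
    "ERROR_TYPES",
    "angle_sequence",
    "animate_chain",
    "trajectory_to_imu_data",
    "simulate_magnetometer",
    "add_noise",
    "apply_calibration_error",
    "sweep_grid",
    "resimulate_from_trajectory",
    "simulate_arm_sequence",
]

#: Global gravity vector (m/s^2); global z points up, opposite gravity.
GRAVITY = np.array([0.0, 0.0, -9.81])


@dataclass
class AngleSequenceParams:
    """Excitation sampling: one 2*pi period in ``n_samples`` steps of ``T``."""

    n_samples: int = 629
    sampling_time: float = 0.01

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least two samples")
        if self.sampling_time <= 0:
            raise ValueError("sampling time must be positive")


def angle_sequence(params: AngleSequenceParams | None = None) -> np.ndarray:
    """The per-DoF excitation angle series (radians).

    ``phi(beta_t) = sin(beta_t/2) * sin(beta_t) * pi`` with
    ``beta_t = 2*pi*t/n``, ``t = 0..n-1``.  The extremum of the continuous
    curve is ``4/(3*sqrt(3)) * pi ~= 2.418 rad ~= 138.6 deg``, i.e. the
    sequence samples a ±139 deg range of motion.
    """
    params = params or AngleSequenceParams()
    beta = 2.0 * np.pi * np.arange(params.n_samples) / params.n_samples
    return np.sin(beta / 2.0) * np.sin(beta) * np.pi


@dataclass
class MotionTrajectory:
    """Ground-truth poses over time for every segment and IMU.

    Quaternion arrays have shape ``(n_frames, n_t, 4)`` and position arrays
    ``(n_frames, n_t, 3)``.
    """

    t: np.ndarray
    seg_quat: np.ndarray
    seg_pos: np.ndarray
    imu_quat: np.ndarray
    imu_pos: np.ndarray
    sampling_time: float

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def n_segments(self) -> int:
        return self.seg_quat.shape[0]


@dataclass
class IMUDataset:
    """Per-IMU gyroscope/accelerometer (and optional magnetometer) series.

    ``gyr``/``acc`` have shape ``(n_imus, n_t, 3)`` (rad/s, m/s^2); ``mag``
    is either ``None`` or unit vectors of the same shape.
    """

    t: np.ndarray
    gyr: np.ndarray
    acc: np.ndarray
    mag: np.ndarray | None
    sampling_time: float

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def n_imus(self) -> int:
        return self.gyr.shape[0]

    @property
    def has_mag(self) -> bool:
        return self.mag is not None

    def without_mag(self) -> "IMUDataset":
        return IMUDataset(self.t, self.gyr, self.acc, None, self.sampling_time)


@dataclass
class NoiseConfig:
    """I.i.d. zero-mean Gaussian sensor noise, reproducible from ``seed``."""

    sigma_gyro: float = 0.01  # rad/s
    sigma_acc: float = 0.05  # m/s^2
    sigma_mag: float = 0.01  # unitless, applied per component then renormalized
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_gyro, self.sigma_acc, self.sigma_mag) < 0:
            raise ValueError("noise standard deviations must be non-negative")


ERROR_TYPES = ("p_along", "p_out", "seg_length", "q_along", "q_out")


@dataclass
class CalibrationErrorSpec:
    """One injected model-calibration error.

    ``magnitude`` is meters for the translational types (``p_along``,
    ``p_out``, ``seg_length``) and degrees for the rotational types
    (``q_along``, ``q_out``).  The error targets the middle segment by
    default, matching the sweep study.
    """

    type: str
    magnitude: float
    segment: int = 1

    def __post_init__(self) -> None:
        if self.type not in ERROR_TYPES:
            raise ValueError(f"unknown calibration error type {self.type!r}")


def animate_chain(model: BodyModel, angles: np.ndarray, sampling_time: float = 0.01) -> MotionTrajectory:
    """Drive the chain with per-DoF angle series and record all global poses.

    ``angles`` is ``(n_t, n_dofs)`` or ``(n_t,)`` (broadcast to every DoF).
    """
    if model.dh_table is None:
        raise ValueError("model has no DH table")
    angles = np.asarray(angles, dtype=float)
    if angles.ndim == 1:
        angles = np.repeat(angles[:, None], model.n_dofs, axis=1)
    if angles.shape[1] != model.n_dofs:
        raise ValueError(f"expected {model.n_dofs} DoF columns, got {angles.shape[1]}")
    n_t = angles.shape[0]
    n = model.n_segments
    seg_q = np.zeros((n, n_t, 4))
    seg_p = np.zeros((n, n_t, 3))
    imu_q = np.zeros((n, n_t, 4))
    imu_p = np.zeros((n, n_t, 3))
    for k in range(n_t):
        seg, imu = chain_fk_matrices(model, angles[k])
        for i in range(n):
            seg_q[i, k] = matrix_to_quat(seg[i, :3, :3])
            seg_p[i, k] = seg[i, :3, 3]
            imu_q[i, k] = matrix_to_quat(imu[i, :3, :3])
            imu_p[i, k] = imu[i, :3, 3]
    t = np.arange(n_t) * sampling_time
    return MotionTrajectory(t, seg_q, seg_p, imu_q, imu_p, sampling_time)


def _angular_velocity(q: np.ndarray, T: float) -> np.ndarray:
    """Body-frame angular velocity from a quaternion series ``(n_t, 4)``.

    Central scheme: ``omega_t = 2*log(q_{t-1}* ⊙ q_{t+1}) / (2T)``; one-sided
    at the ends.  Second-order accurate in the interior.
    """
    n = q.shape[0]
    om = np.zeros((n, 3))
    if n < 2:
        return om
    om[1:-1] = 2.0 * qlog(qmul(qconj(q[:-2]), q[2:])) / (2.0 * T)
    # second-order one-sided ends: extrapolate the midpoint rates
    half = 2.0 * qlog(qmul(qconj(q[:-1]), q[1:])) / T  # omega at t+1/2
    om[0] = 1.5 * half[0] - 0.5 * half[1]
    om[-1] = 1.5 * half[-1] - 0.5 * half[-2]
    return om


def trajectory_to_imu_data(
    traj: MotionTrajectory,
    gravity: np.ndarray = GRAVITY,
    magnetometer: bool = True,
) -> IMUDataset:
    """Differentiate IMU pose trajectories into noise-free strapdown data.

    Gyroscope: quaternion central differences expressed in the IMU frame.
    Accelerometer: ``y_a = R_GI^T (p_ddot_G - g_G)`` with second central
    differences of the IMU positions (one-sided at the ends).
    """
    if traj.n_samples < 3:
        raise ValueError("need at least three samples to differentiate")
    T = traj.sampling_time
    n_imu, n_t = traj.imu_quat.shape[0], traj.n_samples
    gyr = np.zeros((n_imu, n_t, 3))
    acc = np.zeros((n_imu, n_t, 3))
    for i in range(n_imu):
        q = traj.imu_quat[i]
        p = traj.imu_pos[i]
        gyr[i] = _angular_velocity(q, T)
        pdd = np.zeros((n_t, 3))
        pdd[1:-1] = (p[2:] - 2.0 * p[1:-1] + p[:-2]) / T**2
        if n_t >= 4:  # second-order one-sided second differences at the ends
            pdd[0] = (2.0 * p[0] - 5.0 * p[1] + 4.0 * p[2] - p[3]) / T**2
            pdd[-1] = (2.0 * p[-1] - 5.0 * p[-2] + 4.0 * p[-3] - p[-4]) / T**2
        else:
            pdd[0] = pdd[1]
            pdd[-1] = pdd[-2]
        acc[i] = qrotate(qconj(q), pdd - gravity)
    mag = simulate_magnetometer(traj) if magnetometer else None
    return IMUDataset(traj.t.copy(), gyr, acc, mag, T)


def simulate_magnetometer(traj: MotionTrajectory) -> np.ndarray:
    """Artificial magnetometer: the global x-axis seen from each IMU frame.

    ``y_m = R_IG (1,0,0)^T``; unit norm by construction, shape
    ``(n_imus, n_t, 3)``.
    """
    x = np.array([1.0, 0.0, 0.0])
    return qrotate(qconj(traj.imu_quat), x)


def add_noise(data: IMUDataset, cfg: NoiseConfig) -> IMUDataset:
    """Additive Gaussian sensor noise; magnetometer renormalized afterwards."""
    rng = np.random.default_rng(cfg.seed)
    gyr = data.gyr + cfg.sigma_gyro * rng.standard_normal(data.gyr.shape)
    acc = data.acc + cfg.sigma_acc * rng.standard_normal(data.acc.shape)
    mag = None
    if data.mag is not None:
        mag = data.mag + cfg.sigma_mag * rng.standard_normal(data.mag.shape)
        mag = mag / np.linalg.norm(mag, axis=-1, keepdims=True)
    return IMUDataset(data.t.copy(), gyr, acc, mag, data.sampling_time)


def apply_calibration_error(model: BodyModel, spec: CalibrationErrorSpec) -> BodyModel:
    """Return a copy of ``model`` with one calibration error injected.

    Translational types shift the I2S position along the bone (``p_along``,
    segment z) or perpendicular to it (``p_out``, segment x), or rescale the
    bone length (``seg_length``: distal endpoint and the chain's bone
    translation).  Rotational types (degrees) rotate the I2S orientation
    about the segment z-axis (``q_along``) or the IMU x-axis (``q_out``).
    """
    out = model.copy()
    i = spec.segment
    m = float(spec.magnitude)
    cal = out.calibrations[i]
    if spec.type == "p_along":
        cal.r_IS = cal.r_IS + np.array([0.0, 0.0, m])
    elif spec.type == "p_out":
        cal.r_IS = cal.r_IS + np.array([m, 0.0, 0.0])
    elif spec.type == "seg_length":
        seg = out.segments[i]
        seg.length = seg.length + m
        seg.p_dist = seg.p_prox + np.array([0.0, 0.0, seg.length])
        if out.dh_table is not None:
            for row in out.dh_table:
                if row.bone == i:
                    row.d += m
    elif spec.type == "q_along":
        delta = qexp(np.array([0.0, 0.0, np.radians(m) / 2.0]))
        cal.q_SI = qnormalize(qmul(delta, cal.q_SI))
    elif spec.type == "q_out":
        delta = qexp(np.array([np.radians(m) / 2.0, 0.0, 0.0]))
        cal.q_SI = qnormalize(qmul(cal.q_SI, delta))
    return out


def sweep_grid(segment: int = 1) -> list[CalibrationErrorSpec]:
    """The calibration-error study grid: 120 non-zero error magnitudes.

    ±2..±30 deg in 2 deg steps (30 values) for each rotational type and
    ±0.02..±0.2 m in 0.02 m steps (20 values) for each translational type.
    """
    specs: list[CalibrationErrorSpec] = []
    rot = [d for d in range(-30, 31, 2) if d != 0]
    trans = [round(0.02 * k, 10) for k in range(-10, 11) if k != 0]
    for typ in ("p_along", "p_out", "seg_length"):
        specs += [CalibrationErrorSpec(typ, m, segment) for m in trans]
    for typ in ("q_along", "q_out"):
        specs += [CalibrationErrorSpec(typ, float(d), segment) for d in rot]
    return specs


def resimulate_from_trajectory(
    traj: MotionTrajectory,
    cutoff_hz: float = 10.0,
    order: int = 4,
    gravity: np.ndarray = GRAVITY,
    magnetometer: bool = True,
) -> IMUDataset:
    """Low-pass the IMU pose trajectories, then differentiate to IMU data.

    Zero-phase Butterworth filtering (``filtfilt``) keeps the re-simulated
    data in feasible ranges; quaternion components are filtered and
    renormalized.
    """
    from scipy.signal import butter, filtfilt

    fs = 1.0 / traj.sampling_time
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must lie below the Nyquist frequency")
    b, a = butter(order, cutoff_hz, fs=fs)
    imu_p = filtfilt(b, a, traj.imu_pos, axis=1)
    imu_q = filtfilt(b, a, traj.imu_quat, axis=1)
    imu_q = imu_q / np.linalg.norm(imu_q, axis=-1, keepdims=True)
    smooth = MotionTrajectory(
        traj.t, traj.seg_quat, traj.seg_pos, imu_q, imu_p, traj.sampling_time
    )
    return trajectory_to_imu_data(smooth, gravity, magnetometer)


def simulate_arm_sequence(
    model: BodyModel | None = None,
    params: AngleSequenceParams | None = None,
    calibration_error: CalibrationErrorSpec | None = None,
    noise: NoiseConfig | None = None,
    magnetometer: bool = True,
    gravity: np.ndarray = GRAVITY,
) -> tuple[MotionTrajectory, IMUDataset]:
    """End-to-end study sequence: ground truth plus (optionally erroneous) data.

    Returns ``(truth, data)`` where ``truth`` is the trajectory of the
    *nominal* model and ``data`` was generated from the model with
    ``calibration_error`` injected (if any).  Trackers are run with the
    nominal model and scored against ``truth``.
    """
    model = model or build_arm_model()
    params = params or AngleSequenceParams()
    phi = angle_sequence(params)
    truth = animate_chain(model, phi, params.sampling_time)
    if calibration_error is not None:
        perturbed = apply_calibration_error(model, calibration_error)
        traj = animate_chain(perturbed, phi, params.sampling_time)
    else:
        traj = truth
    data = trajectory_to_imu_data(traj, gravity, magnetometer)
    if noise is not None:
        data = add_noise(data, noise)
    return truth, data
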