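"""Extended Kalman filter trackers.

Three filters share one predict/update loop and differ in their state space:

* :class:`QuattrackerIMU` — free IMU poses; constant angular velocity and
  constant linear acceleration dynamics.
* :class:`QuattrackerSegment` — free segment poses; constant angular and
  linear acceleration dynamics, with the IMU quantities obtained by rigid
  transport through the I2S calibration.
* :class:`Chaintracker` — joint angles of the DH chain with per-DoF constant
  angular acceleration dynamics; measurement prediction by virtual-time
  finite differencing of the forward kinematics.

Quaternions are kept in the state at full four components but linearized
multiplicatively: the filter covariance lives on a 3-DoF attitude error
``q = q_hat ⊙ exp(delta/2)`` (error-state / MEKF treatment), which avoids
the rank deficiency of a direct four-component covariance.  Measurement
Jacobians are analytic for the two free-segments filters and batched
central differences for the chain filter; the dynamics Jacobians are
analytic (the transition is linear except for the attitude block).

Joint connectivity and the global anchor enter as pseudo-measurements
stacked with the sensor measurements in a single update.  The stack is
grouped by type: accelerometer rows, gyroscope rows, (valid) magnetometer
rows, joint rows, anchor rows — 7 rows per IMU with magnetometer, 6
without, plus 3 per joint and 3 for the anchor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .body import BodyModel, chain_fk_batch, chain_fk_matrices
from .measurements import MAG_HORIZONTAL_TOL, MeasurementNoise
from .quat import (
    matrix_to_quat,
    qconj,
    qexp,
    qlog,
    qmul,
    qnormalize,
    qrotate,
    quat_to_matrix,
    rotvec_from_matrix,
    skew,
    triad,
)
from .results import TrackingResult
from .simulate import GRAVITY, IMUDataset

__all__ = [
    "EKFConfig",
    "QuattrackerIMU",
    "QuattrackerSegment",
    "Chaintracker",
    "initialize_orientations",
    "place_segments_from_anchor",
    "chain_ik_init",
]


@dataclass
class EKFConfig:
    """Tuning of the EKF trackers.

    Process noise levels drive the highest derivative of each motion model:
    ``sigma_jerk`` (m/s^3) the linear acceleration random walk (entering as
    ``T*sigma`` per step), ``sigma_omega_walk`` (rad/s^2) the angular
    velocity walk of the IMU-centered filter, ``sigma_alpha_walk`` (rad/s^2
    per step) the angular acceleration walk of the segment-centered filter
    and ``sigma_theta_ddot_walk`` (rad/s^2 per step) the per-DoF angular
    acceleration walk of the chain filter.
    """

    noise: MeasurementNoise = field(default_factory=MeasurementNoise)
    use_magnetometer: bool = True
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    sigma_jerk: float = 200.0
    sigma_omega_walk: float = 100.0
    sigma_alpha_walk: float = 20.0
    sigma_theta_ddot_walk: float = 5.0
    init_heading: float = 0.0  # rad; used when no magnetometer sample exists
    jacobian_step: float = 1e-6
    fk_time_step: float = 1e-3  # virtual time step for chain differentiation

    def __post_init__(self) -> None:
        self.gravity = np.asarray(self.gravity, dtype=float).reshape(3)


# ---------------------------------------------------------------------------
# shared initialization helpers


def initialize_orientations(data: IMUDataset, config) -> np.ndarray:
    """Initial IMU orientations ``q_GI`` from the first sample via TRIAD.

    If the dataset carries no magnetometer channel, the tilt is taken from
    the accelerometer and the heading from ``config.init_heading`` (0 if the
    config has none).
    """
    heading = getattr(config, "init_heading", 0.0)
    n = data.n_imus
    out = np.zeros((n, 4))
    for i in range(n):
        if data.mag is not None:
            out[i] = triad(data.acc[i, 0], data.mag[i, 0])
        else:
            out[i] = _tilt_and_heading(data.acc[i, 0], heading)
    return out


def _tilt_and_heading(y_a: np.ndarray, heading: float) -> np.ndarray:
    """Attitude from gravity plus an assumed yaw (no-magnetometer fallback)."""
    up = np.asarray(y_a, dtype=float)
    nrm = np.linalg.norm(up)
    if nrm < 1e-9:
        raise ValueError("cannot initialize tilt from a zero accelerometer sample")
    up = up / nrm
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(up, z))
    axis = np.cross(up, z)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        q_tilt = np.array([1.0, 0, 0, 0]) if c > 0 else qexp(np.array([np.pi / 2, 0.0, 0.0]))
    else:
        q_tilt = qexp(0.5 * np.arctan2(s, c) * axis / s)
    q_yaw = qexp(np.array([0.0, 0.0, heading / 2.0]))
    return qnormalize(qmul(q_yaw, q_tilt))


def place_segments_from_anchor(model: BodyModel, seg_quat: np.ndarray) -> np.ndarray:
    """Segment origins satisfying the joint constraints exactly.

    Starting from the anchored segment, each child origin is placed at its
    parent's matched endpoint, so the connectivity residuals vanish by
    construction.
    """
    n = model.n_segments
    pos = np.full((n, 3), np.nan)
    a = model.anchor
    pos[a.segment] = a.P_G - qrotate(seg_quat[a.segment], a.p_S)
    remaining = list(model.joints)
    while remaining:
        progressed = False
        for j in list(remaining):
            if not np.any(np.isnan(pos[j.parent])):
                pp = pos[j.parent] + qrotate(seg_quat[j.parent], model.endpoint(j.parent, j.parent_point))
                pos[j.child] = pp - qrotate(seg_quat[j.child], model.endpoint(j.child, j.child_point))
                remaining.remove(j)
                progressed = True
            elif not np.any(np.isnan(pos[j.child])):
                cp = pos[j.child] + qrotate(seg_quat[j.child], model.endpoint(j.child, j.child_point))
                pos[j.parent] = cp - qrotate(seg_quat[j.parent], model.endpoint(j.parent, j.parent_point))
                remaining.remove(j)
                progressed = True
        if not progressed:
            raise ValueError("joint graph is not connected to the anchored segment")
    return pos


def chain_ik_init(model: BodyModel, q_GI: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
    """Chain angles whose forward kinematics best match given IMU orientations.

    Minimizes the rotation-vector mismatch between the FK-predicted and the
    supplied IMU orientations (same minimizer as the Frobenius-norm
    orientation objective) with a Levenberg-Marquardt least-squares solve.
    """
    from scipy.optimize import least_squares

    nd = model.n_dofs

    def resid(x: np.ndarray) -> np.ndarray:
        _, imu = chain_fk_matrices(model, x)
        out = np.zeros(3 * len(q_GI))
        for i in range(len(q_GI)):
            q_fk = matrix_to_quat(imu[i, :3, :3])
            out[3 * i : 3 * i + 3] = 2.0 * qlog(qmul(qconj(q_fk), q_GI[i]))
        return out

    x0 = np.zeros(nd) if x0 is None else np.asarray(x0, dtype=float)
    sol = least_squares(resid, x0, method="lm", xtol=1e-12, ftol=1e-12)
    if not sol.success:  # pragma: no cover - LM on this smooth problem converges
        raise RuntimeError(f"chain inverse kinematics did not converge: {sol.message}")
    return sol.x


def _mag_gradient_row(u: np.ndarray) -> np.ndarray:
    """Gradient of atan2(u_y, u_x) with respect to u."""
    den = u[0] ** 2 + u[1] ** 2
    return np.array([-u[1], u[0], 0.0]) / den


def chain_kinematics_snapshot(model: BodyModel, th, thd, thdd, h: float = 1e-3) -> dict:
    """Segment and IMU kinematics implied by one chain state.

    Differentiates the forward kinematics over a virtual time step ``h``
    (propagating ``thd``/``thdd``), returning for both ``"seg"`` and
    ``"imu"`` frames: rotation matrices ``R``, positions ``p``, velocities
    ``v``, accelerations ``a`` and body-frame angular velocities ``omega``.
    """
    th = np.asarray(th, dtype=float)
    thd = np.asarray(thd, dtype=float)
    thdd = np.asarray(thdd, dtype=float)
    curv = 0.5 * h * h * thdd
    configs = np.stack([th - h * thd + curv, th, th + h * thd + curv])
    seg, imu = chain_fk_batch(model, configs)  # (3, n, 4, 4)
    out = {}
    for key, arr in (("seg", seg), ("imu", imu)):
        Rm, Rc, Rp = arr[0, :, :3, :3], arr[1, :, :3, :3], arr[2, :, :3, :3]
        pm, pc, pp = arr[0, :, :3, 3], arr[1, :, :3, 3], arr[2, :, :3, 3]
        out[key] = {
            "R": Rc.copy(),
            "p": pc.copy(),
            "v": (pp - pm) / (2.0 * h),
            "a": (pp - 2.0 * pc + pm) / h**2,
            "omega": rotvec_from_matrix(np.einsum("nji,njk->nik", Rm, Rp)) / (2.0 * h),
        }
    return out


def fit_initial_chain_state(
    data: IMUDataset, model: BodyModel, config: EKFConfig, n_fit: int = 3
):
    """Initial chain state (angles, rates, accelerations) from the first samples.

    TRIAD attitudes anchor the chain angles via inverse kinematics; a short
    least-squares refinement over the first ``n_fit`` samples then finds the
    angle rates and accelerations (and corrects the angles) that explain the
    accelerometer/gyroscope data through the chain model, assuming constant
    angular acceleration over that span.  This removes the tilt bias that
    body acceleration induces in a plain TRIAD fix — essential when a
    sequence does not start at rest, and doubly so without a magnetometer,
    where a transient attitude excursion turns into a permanent
    (unobservable) global yaw offset.  Weak priors (angles near the IK fix,
    rates/accelerations shrunk toward zero) keep the problem well posed.
    The magnetometer heading rows use the data whenever the channel exists,
    regardless of the tracking-time magnetometer setting.
    """
    from scipy.optimize import least_squares

    nz = config.noise
    q_tri = initialize_orientations(data, config)
    th0 = chain_ik_init(model, q_tri)
    nd = model.n_dofs
    n_fit = int(min(max(n_fit, 1), data.n_samples))
    T = data.sampling_time
    yhat = None
    if data.mag is not None:
        m0 = data.mag[:, :n_fit]
        yhat = m0 / np.linalg.norm(m0, axis=-1, keepdims=True)

    def resid(x: np.ndarray) -> np.ndarray:
        th, thd, thdd = x[:nd], x[nd : 2 * nd], x[2 * nd :]
        parts = []
        for s in range(n_fit):
            t = s * T
            th_s = th + t * thd + 0.5 * t**2 * thdd
            thd_s = thd + t * thdd
            kin = chain_kinematics_snapshot(model, th_s, thd_s, thdd,
                                            config.fk_time_step)["imu"]
            pred_a = np.einsum("nji,nj->ni", kin["R"], kin["a"] - config.gravity)
            parts.append((data.acc[:, s] - pred_a).ravel() / nz.sigma_acc)
            parts.append((data.gyr[:, s] - kin["omega"]).ravel() / nz.sigma_gyro)
            if yhat is not None:
                u = np.einsum("nij,nj->ni", kin["R"], yhat[:, s])
                parts.append(np.arctan2(u[:, 1], u[:, 0]) / nz.sigma_mag)
        parts.append((th - th0) / np.radians(45.0))
        parts.append(thd / 20.0)
        parts.append(thdd / 200.0)
        return np.concatenate(parts)

    x0 = np.concatenate([th0, np.zeros(2 * nd)])
    # soft-L1 loss: rows from a miscalibrated IMU are outliers against the
    # consistent majority and must not drag the fit
    sol = least_squares(resid, x0, method="trf", loss="soft_l1", f_scale=2.0,
                        xtol=1e-12, ftol=1e-12)
    return sol.x[:nd], sol.x[nd : 2 * nd], sol.x[2 * nd :]


# ---------------------------------------------------------------------------
# base filter


class _EKFTracker:
    """Shared EKF predict/update loop over an :class:`IMUDataset`."""

    method = "ekf"
    _include_constraints = True

    def __init__(self, data: IMUDataset, model: BodyModel, config: EKFConfig | None = None):
        self.data = data
        self.model = model
        self.config = config or EKFConfig()
        self.T = data.sampling_time
        self.n_seg = model.n_segments
        if data.n_imus != model.n_segments:
            raise ValueError("dataset and model disagree on the number of IMUs")
        self._use_mag = self.config.use_magnetometer and data.mag is not None
        self._g = self.config.gravity

    # subclass interface -------------------------------------------------
    @property
    def dim(self) -> int:  # error-state dimension
        raise NotImplementedError

    def _initialize(self):
        raise NotImplementedError

    def _predict_mean(self, mean):
        raise NotImplementedError

    def _transition(self, mean):
        """Return ``(F, Q)`` linearized at ``mean`` (before prediction)."""
        raise NotImplementedError

    def _boxplus(self, mean, delta: np.ndarray):
        raise NotImplementedError

    def _imu_quantities(self, mean):
        """Return ``(acc_G, q_GI, omega_I)``, shapes ``(n,3),(n,4),(n,3)``."""
        raise NotImplementedError

    def _segment_poses(self, mean):
        """Return ``(q_GS, S_G)``, shapes ``(n,4),(n,3)``."""
        raise NotImplementedError

    def _measurement_H(self, mean, k: int, mag_mask) -> np.ndarray:
        """``d(prediction)/d(delta)``; default: central differences."""
        return -self._numeric_J(mean, k, mag_mask)

    # residual stack -----------------------------------------------------
    def _mag_unit(self, k: int) -> np.ndarray:
        m = self.data.mag[:, k]
        return m / np.linalg.norm(m, axis=-1, keepdims=True)

    def _residual(self, mean, k: int, mag_mask: np.ndarray | None = None):
        """Observed-minus-predicted stack at sample ``k``.

        Returns ``(r, r_std, mag_mask)`` where ``mag_mask`` marks IMUs whose
        magnetometer row is valid (horizontal projection observable).
        """
        nz = self.config.noise
        acc_G, q_GI, om_I = self._imu_quantities(mean)
        parts: list[np.ndarray] = []
        stds: list[np.ndarray] = []
        pred_a = qrotate(qconj(q_GI), acc_G - self._g)
        parts.append((self.data.acc[:, k] - pred_a).ravel())
        stds.append(np.full(3 * self.n_seg, nz.sigma_acc))
        parts.append((self.data.gyr[:, k] - om_I).ravel())
        stds.append(np.full(3 * self.n_seg, nz.sigma_gyro))
        if self._use_mag:
            u = qrotate(q_GI, self._mag_unit(k))
            if mag_mask is None:
                mag_mask = np.hypot(u[:, 0], u[:, 1]) > MAG_HORIZONTAL_TOL
            parts.append(-np.arctan2(u[mag_mask, 1], u[mag_mask, 0]))
            stds.append(np.full(int(mag_mask.sum()), nz.sigma_mag))
        if self._include_constraints:
            q_GS, S_G = self._segment_poses(mean)
            for j in self.model.joints:
                gap = (
                    S_G[j.parent] + qrotate(q_GS[j.parent], self.model.endpoint(j.parent, j.parent_point))
                ) - (S_G[j.child] + qrotate(q_GS[j.child], self.model.endpoint(j.child, j.child_point)))
                parts.append(-gap)
                stds.append(np.full(3, nz.sigma_p))
            a = self.model.anchor
            parts.append(-(S_G[a.segment] + qrotate(q_GS[a.segment], a.p_S) - a.P_G))
            stds.append(np.full(3, nz.sigma_anchor))
        return np.concatenate(parts), np.concatenate(stds), mag_mask

    def _numeric_J(self, mean, k: int, mag_mask) -> np.ndarray:
        """``d(residual)/d(delta)`` by central differences (reference path)."""
        eps = self.config.jacobian_step
        r0, _, _ = self._residual(mean, k, mag_mask)
        J = np.zeros((r0.shape[0], self.dim))
        delta = np.zeros(self.dim)
        for c in range(self.dim):
            delta[c] = eps
            rp, _, _ = self._residual(self._boxplus(mean, delta), k, mag_mask)
            delta[c] = -eps
            rm, _, _ = self._residual(self._boxplus(mean, delta), k, mag_mask)
            delta[c] = 0.0
            J[:, c] = (rp - rm) / (2.0 * eps)
        return J

    # main loop ----------------------------------------------------------
    def fit(self) -> TrackingResult:
        data = self.data
        n_t = data.n_samples
        mean, P = self._initialize()
        seg_q = np.zeros((self.n_seg, n_t, 4))
        seg_p = np.zeros((self.n_seg, n_t, 3))
        innov = np.zeros(n_t)
        for k in range(n_t):
            if k > 0:
                F, Q = self._transition(mean)
                mean = self._predict_mean(mean)
                P = F @ P @ F.T + Q
                P = 0.5 * (P + P.T)
            mean, P, innov[k] = self._update(mean, P, k)
            q, p = self._segment_poses(mean)
            seg_q[:, k] = q
            seg_p[:, k] = p
        self._check_psd(P)
        return TrackingResult(
            method=self.method,
            t=data.t.copy(),
            seg_quat=seg_q,
            seg_pos=seg_p,
            diagnostics={
                "mean_innovation_norm": float(innov.mean()),
                "max_innovation_norm": float(innov.max()),
                "innovation_norms": innov,
            },
            config=self.config,
        )

    def _update(self, mean, P, k: int):
        r0, r_std, mag_mask = self._residual(mean, k)
        H = self._measurement_H(mean, k, mag_mask)
        S = H @ P @ H.T + np.diag(r_std**2)
        K = np.linalg.solve(S, H @ P).T
        delta = K @ r0
        mean = self._boxplus(mean, delta)
        IKH = np.eye(self.dim) - K @ H
        P = IKH @ P @ IKH.T + (K * r_std**2) @ K.T  # Joseph form
        P = 0.5 * (P + P.T)
        return mean, P, float(np.linalg.norm(r0))

    @staticmethod
    def _check_psd(P: np.ndarray) -> None:
        ev = np.linalg.eigvalsh(P)
        if ev.min() < -1e-8 * max(1.0, ev.max()):
            raise FloatingPointError("covariance lost positive semi-definiteness")

    def _constraint_H_free(self, H: np.ndarray, row0: int, per: int,
                           pos_col: int, att_col: int, frames: np.ndarray,
                           lever_imu_frame) -> None:
        """Fill joint/anchor rows for free-state filters.

        ``frames`` are the rotation matrices whose attitude error the state
        carries; ``lever_imu_frame(i, p)`` maps a segment-frame lever arm to
        the error frame.  The endpoint expression is
        ``pos_i + R_i * lever``, so ``d/dpos = I`` and
        ``d/ddelta = -R_i skew(lever)``.
        """
        r = row0
        for j in self.model.joints:
            for sgn, i, which in ((1.0, j.parent, j.parent_point), (-1.0, j.child, j.child_point)):
                lever = lever_imu_frame(i, self.model.endpoint(i, which))
                o = per * i
                H[r : r + 3, o + pos_col : o + pos_col + 3] += sgn * np.eye(3)
                H[r : r + 3, o + att_col : o + att_col + 3] += -sgn * frames[i] @ skew(lever)
            r += 3
        a = self.model.anchor
        lever = lever_imu_frame(a.segment, a.p_S)
        o = per * a.segment
        H[r : r + 3, o + pos_col : o + pos_col + 3] = np.eye(3)
        H[r : r + 3, o + att_col : o + att_col + 3] = -frames[a.segment] @ skew(lever)


# ---------------------------------------------------------------------------
# Quattracker IMU


@dataclass
class _FreeIMUState:
    p: np.ndarray  # (n,3) IMU positions, global
    v: np.ndarray
    a: np.ndarray
    q: np.ndarray  # (n,4) q_GI
    w: np.ndarray  # (n,3) angular velocity, IMU frame

    def copy(self) -> "_FreeIMUState":
        return _FreeIMUState(*(x.copy() for x in (self.p, self.v, self.a, self.q, self.w)))


class QuattrackerIMU(_EKFTracker):
    """IMU-centered free-segments EKF (constant angular velocity model).

    State per segment: IMU position/velocity/acceleration in the global
    frame, IMU orientation quaternion and IMU-frame angular velocity.
    Segment poses are recovered through the (assumed error-free) I2S
    calibrations.
    """

    method = "quattracker-imu"
    _per = 15

    @property
    def dim(self) -> int:
        return self._per * self.n_seg

    def _initialize(self):
        if self.model.dh_table is not None and self.model.n_dofs:
            th, thd, thdd = fit_initial_chain_state(self.data, self.model, self.config)
            kin = chain_kinematics_snapshot(self.model, th, thd, thdd,
                                            self.config.fk_time_step)["imu"]
            q_GI = np.array([matrix_to_quat(R) for R in kin["R"]])
            mean = _FreeIMUState(kin["p"], kin["v"], kin["a"], q_GI, kin["omega"])
        else:  # plain TRIAD fallback for models without a chain parametrization
            q_GI = initialize_orientations(self.data, self.config)
            q_SI = np.array([c.q_SI for c in self.model.calibrations])
            q_GS = qmul(q_GI, qconj(q_SI))
            S = place_segments_from_anchor(self.model, q_GS)
            r_IS = np.array([c.r_IS for c in self.model.calibrations])
            p = S + qrotate(q_GS, r_IS)
            mean = _FreeIMUState(p, np.zeros_like(p), np.zeros_like(p), q_GI, np.zeros_like(p))
        P = np.diag(np.tile(np.concatenate([
            np.full(3, 1e-2**2), np.full(3, 0.5**2), np.full(3, 2.0**2),
            np.full(3, np.radians(5.0) ** 2), np.full(3, 0.5**2),
        ]), self.n_seg))
        return mean, P

    def _predict_mean(self, s: _FreeIMUState) -> _FreeIMUState:
        T = self.T
        out = s.copy()
        out.p = s.p + T * s.v + 0.5 * T**2 * s.a
        out.v = s.v + T * s.a
        out.q = qnormalize(qmul(s.q, qexp(0.5 * T * s.w)))
        return out

    def _transition(self, s: _FreeIMUState):
        T = self.T
        F = np.eye(self.dim)
        Q = np.zeros((self.dim, self.dim))
        eye = np.eye(3)
        for i in range(self.n_seg):
            o = self._per * i
            F[o : o + 3, o + 3 : o + 6] = T * eye
            F[o : o + 3, o + 6 : o + 9] = 0.5 * T**2 * eye
            F[o + 3 : o + 6, o + 6 : o + 9] = T * eye
            F[o + 9 : o + 12, o + 9 : o + 12] = quat_to_matrix(qexp(-0.5 * T * s.w[i]))
            F[o + 9 : o + 12, o + 12 : o + 15] = T * eye
            Q[o + 6 : o + 9, o + 6 : o + 9] = (T * self.config.sigma_jerk) ** 2 * eye
            Q[o + 12 : o + 15, o + 12 : o + 15] = (T * self.config.sigma_omega_walk) ** 2 * eye
        return F, Q

    def _boxplus(self, s: _FreeIMUState, delta: np.ndarray) -> _FreeIMUState:
        d = delta.reshape(self.n_seg, self._per)
        out = s.copy()
        out.p = s.p + d[:, 0:3]
        out.v = s.v + d[:, 3:6]
        out.a = s.a + d[:, 6:9]
        out.q = qnormalize(qmul(s.q, qexp(0.5 * d[:, 9:12])))
        out.w = s.w + d[:, 12:15]
        return out

    def _imu_quantities(self, s: _FreeIMUState):
        return s.a, s.q, s.w

    def _segment_poses(self, s: _FreeIMUState):
        q_SI = np.array([c.q_SI for c in self.model.calibrations])
        q_GS = qmul(s.q, qconj(q_SI))
        r_IS = np.array([c.r_IS for c in self.model.calibrations])
        return q_GS, s.p - qrotate(q_GS, r_IS)

    def _measurement_H(self, s: _FreeIMUState, k: int, mag_mask) -> np.ndarray:
        n = self.n_seg
        n_mag = int(mag_mask.sum()) if (self._use_mag and mag_mask is not None) else 0
        rows = 6 * n + n_mag + 3 * len(self.model.joints) + 3
        H = np.zeros((rows, self.dim))
        R = quat_to_matrix(s.q)  # (n,3,3)
        u_body = np.einsum("nji,nj->ni", R, s.a - self._g)  # R^T (a - g)
        for i in range(n):
            o = self._per * i
            H[3 * i : 3 * i + 3, o + 6 : o + 9] = R[i].T
            H[3 * i : 3 * i + 3, o + 9 : o + 12] = skew(u_body[i])
            r = 3 * n + 3 * i
            H[r : r + 3, o + 12 : o + 15] = np.eye(3)
        if n_mag:
            yhat = self._mag_unit(k)
            r = 6 * n
            for i in np.flatnonzero(mag_mask):
                u = R[i] @ yhat[i]
                H[r, self._per * i + 9 : self._per * i + 12] = _mag_gradient_row(u) @ (
                    -R[i] @ skew(yhat[i])
                )
                r += 1
        R_IS = np.array([quat_to_matrix(qconj(c.q_SI)) for c in self.model.calibrations])
        r_IS = np.array([c.r_IS for c in self.model.calibrations])
        self._constraint_H_free(
            H, 6 * n + n_mag, self._per, 0, 9, R,
            lambda i, p: R_IS[i] @ (p - r_IS[i]),
        )
        return H


# ---------------------------------------------------------------------------
# Quattracker segment


@dataclass
class _FreeSegmentState:
    S: np.ndarray  # (n,3)
    Sd: np.ndarray
    Sdd: np.ndarray
    q: np.ndarray  # (n,4) q_GS
    w: np.ndarray  # (n,3) segment-frame angular velocity
    wd: np.ndarray  # (n,3) segment-frame angular acceleration

    def copy(self) -> "_FreeSegmentState":
        return _FreeSegmentState(*(x.copy() for x in (self.S, self.Sd, self.Sdd, self.q, self.w, self.wd)))


class QuattrackerSegment(_EKFTracker):
    """Segment-centered free-segments EKF (constant angular acceleration).

    Keeping the kinematics in the segment frame requires the angular
    acceleration in the state, because the accelerometer prediction needs
    the IMU acceleration, obtained from the segment acceleration by rigid
    transport: ``a_I = S_dd + R_GS [S(w)S(w) + S(w_dot)] r_IS``
    (centripetal plus Euler terms).
    """

    method = "quattracker-segment"
    _per = 18

    @property
    def dim(self) -> int:
        return self._per * self.n_seg

    def _initialize(self):
        if self.model.dh_table is not None and self.model.n_dofs:
            th, thd, thdd = fit_initial_chain_state(self.data, self.model, self.config)
            kin = chain_kinematics_snapshot(self.model, th, thd, thdd,
                                            self.config.fk_time_step)["seg"]
            q_GS = np.array([matrix_to_quat(R) for R in kin["R"]])
            mean = _FreeSegmentState(kin["p"], kin["v"], kin["a"], q_GS,
                                     kin["omega"], np.zeros_like(kin["p"]))
        else:
            q_GI = initialize_orientations(self.data, self.config)
            q_SI = np.array([c.q_SI for c in self.model.calibrations])
            q_GS = qmul(q_GI, qconj(q_SI))
            S = place_segments_from_anchor(self.model, q_GS)
            z = np.zeros_like(S)
            mean = _FreeSegmentState(S, z.copy(), z.copy(), q_GS, z.copy(), z.copy())
        P = np.diag(np.tile(np.concatenate([
            np.full(3, 1e-2**2), np.full(3, 0.5**2), np.full(3, 2.0**2),
            np.full(3, np.radians(5.0) ** 2), np.full(3, 0.5**2), np.full(3, 20.0**2),
        ]), self.n_seg))
        return mean, P

    def _predict_mean(self, s: _FreeSegmentState) -> _FreeSegmentState:
        T = self.T
        out = s.copy()
        out.S = s.S + T * s.Sd + 0.5 * T**2 * s.Sdd
        out.Sd = s.Sd + T * s.Sdd
        out.q = qnormalize(qmul(s.q, qexp(0.5 * T * s.w + 0.25 * T**2 * s.wd)))
        out.w = s.w + T * s.wd
        return out

    def _transition(self, s: _FreeSegmentState):
        T = self.T
        F = np.eye(self.dim)
        Q = np.zeros((self.dim, self.dim))
        eye = np.eye(3)
        for i in range(self.n_seg):
            o = self._per * i
            F[o : o + 3, o + 3 : o + 6] = T * eye
            F[o : o + 3, o + 6 : o + 9] = 0.5 * T**2 * eye
            F[o + 3 : o + 6, o + 6 : o + 9] = T * eye
            rotvec = T * s.w[i] + 0.5 * T**2 * s.wd[i]
            F[o + 9 : o + 12, o + 9 : o + 12] = quat_to_matrix(qexp(-0.5 * rotvec))
            F[o + 9 : o + 12, o + 12 : o + 15] = T * eye
            F[o + 9 : o + 12, o + 15 : o + 18] = 0.5 * T**2 * eye
            F[o + 12 : o + 15, o + 15 : o + 18] = T * eye
            Q[o + 6 : o + 9, o + 6 : o + 9] = (T * self.config.sigma_jerk) ** 2 * eye
            Q[o + 15 : o + 18, o + 15 : o + 18] = self.config.sigma_alpha_walk**2 * eye
        return F, Q

    def _boxplus(self, s: _FreeSegmentState, delta: np.ndarray) -> _FreeSegmentState:
        d = delta.reshape(self.n_seg, self._per)
        out = s.copy()
        out.S = s.S + d[:, 0:3]
        out.Sd = s.Sd + d[:, 3:6]
        out.Sdd = s.Sdd + d[:, 6:9]
        out.q = qnormalize(qmul(s.q, qexp(0.5 * d[:, 9:12])))
        out.w = s.w + d[:, 12:15]
        out.wd = s.wd + d[:, 15:18]
        return out

    def _imu_quantities(self, s: _FreeSegmentState):
        q_SI = np.array([c.q_SI for c in self.model.calibrations])
        r_IS = np.array([c.r_IS for c in self.model.calibrations])
        # rigid transport of acceleration: centripetal + Euler terms
        transport = np.cross(s.w, np.cross(s.w, r_IS)) + np.cross(s.wd, r_IS)
        acc = s.Sdd + qrotate(s.q, transport)
        q_GI = qmul(s.q, q_SI)
        om_I = qrotate(qconj(q_SI), s.w)
        return acc, q_GI, om_I

    def _segment_poses(self, s: _FreeSegmentState):
        return s.q, s.S

    def _measurement_H(self, s: _FreeSegmentState, k: int, mag_mask) -> np.ndarray:
        n = self.n_seg
        n_mag = int(mag_mask.sum()) if (self._use_mag and mag_mask is not None) else 0
        rows = 6 * n + n_mag + 3 * len(self.model.joints) + 3
        H = np.zeros((rows, self.dim))
        R_GS = quat_to_matrix(s.q)
        R_SI = np.array([quat_to_matrix(c.q_SI) for c in self.model.calibrations])
        r_IS = np.array([c.r_IS for c in self.model.calibrations])
        for i in range(n):
            o = self._per * i
            RSIT = R_SI[i].T
            # accelerometer prediction R_SI^T [R_GS^T (Sdd - g) + u(w, wd)]
            H[3 * i : 3 * i + 3, o + 6 : o + 9] = RSIT @ R_GS[i].T
            H[3 * i : 3 * i + 3, o + 9 : o + 12] = RSIT @ skew(R_GS[i].T @ (s.Sdd[i] - self._g))
            du_dw = -skew(np.cross(s.w[i], r_IS[i])) - skew(s.w[i]) @ skew(r_IS[i])
            H[3 * i : 3 * i + 3, o + 12 : o + 15] = RSIT @ du_dw
            H[3 * i : 3 * i + 3, o + 15 : o + 18] = -RSIT @ skew(r_IS[i])
            r = 3 * n + 3 * i
            H[r : r + 3, o + 12 : o + 15] = RSIT
        if n_mag:
            yhat = self._mag_unit(k)
            r = 6 * n
            for i in np.flatnonzero(mag_mask):
                v = R_SI[i] @ yhat[i]
                u = R_GS[i] @ v
                H[r, self._per * i + 9 : self._per * i + 12] = _mag_gradient_row(u) @ (
                    -R_GS[i] @ skew(v)
                )
                r += 1
        self._constraint_H_free(H, 6 * n + n_mag, self._per, 0, 9, R_GS, lambda i, p: p)
        return H


# ---------------------------------------------------------------------------
# Chaintracker


@dataclass
class _ChainState:
    th: np.ndarray
    thd: np.ndarray
    thdd: np.ndarray

    def copy(self) -> "_ChainState":
        return _ChainState(self.th.copy(), self.thd.copy(), self.thdd.copy())


class Chaintracker(_EKFTracker):
    """Kinematic-chain EKF over joint angles (per-DoF constant angular acc).

    The measurement prediction evaluates the chain forward kinematics at the
    current angles and at two virtual time offsets ``±h`` (propagating the
    state's angle rates), then differentiates the resulting IMU poses to the
    angular velocity and linear acceleration seen by each IMU.  This is
    second-order accurate in ``h`` and keeps the predictor consistent with
    the chain geometry without analytic chain Jacobians; the measurement
    Jacobian is obtained by central differences over the state, batched
    through the vectorized forward kinematics.  Joint connectivity and the
    anchor hold by construction, so no constraint rows are stacked.
    """

    method = "chaintracker"
    _include_constraints = False

    def __init__(self, data: IMUDataset, model: BodyModel, config: EKFConfig | None = None):
        super().__init__(data, model, config)
        if model.dh_table is None:
            raise ValueError("Chaintracker requires a model with a DH table")
        self.n_dofs = model.n_dofs

    @property
    def dim(self) -> int:
        return 3 * self.n_dofs

    def _initialize(self):
        th, thd, thdd = fit_initial_chain_state(self.data, self.model, self.config)
        nd = self.n_dofs
        mean = _ChainState(th, thd, thdd)
        P = np.diag(np.concatenate([
            np.full(nd, np.radians(2.0) ** 2), np.full(nd, 0.5**2), np.full(nd, 10.0**2),
        ]))
        return mean, P

    def _predict_mean(self, s: _ChainState) -> _ChainState:
        T = self.T
        out = s.copy()
        out.th = s.th + T * s.thd + 0.5 * T**2 * s.thdd
        out.thd = s.thd + T * s.thdd
        return out

    def _transition(self, s: _ChainState):
        T = self.T
        nd = self.n_dofs
        eye = np.eye(nd)
        F = np.eye(self.dim)
        F[:nd, nd : 2 * nd] = T * eye
        F[:nd, 2 * nd :] = 0.5 * T**2 * eye
        F[nd : 2 * nd, 2 * nd :] = T * eye
        Q = np.zeros((self.dim, self.dim))
        Q[2 * nd :, 2 * nd :] = self.config.sigma_theta_ddot_walk**2 * eye
        return F, Q

    def _boxplus(self, s: _ChainState, delta: np.ndarray) -> _ChainState:
        nd = self.n_dofs
        out = s.copy()
        out.th = s.th + delta[:nd]
        out.thd = s.thd + delta[nd : 2 * nd]
        out.thdd = s.thdd + delta[2 * nd :]
        return out

    # batched measurement machinery --------------------------------------
    def _state_vec(self, s: _ChainState) -> np.ndarray:
        return np.concatenate([s.th, s.thd, s.thdd])

    def predict_imu_quantities(self, th, thd, thdd):
        """Predicted ``(acc_G, R_GI, omega_I)`` for one chain state."""
        X = np.concatenate([th, thd, thdd])[None, :]
        accG, Rc, om = self._imu_prediction_batch(X)
        return accG[0], Rc[0], om[0]

    def _imu_prediction_batch(self, X: np.ndarray):
        """``X``: (M, 3*nd) stacked states -> per-IMU predicted quantities."""
        nd = self.n_dofs
        h = self.config.fk_time_step
        th, thd, thdd = X[:, :nd], X[:, nd : 2 * nd], X[:, 2 * nd :]
        curv = 0.5 * h**2 * thdd
        configs = np.concatenate([th - h * thd + curv, th, th + h * thd + curv], axis=0)
        _, imu = chain_fk_batch(self.model, configs)  # (3M, n, 4, 4)
        M = X.shape[0]
        imu = imu.reshape(3, M, self.n_seg, 4, 4)
        Rm, Rc, Rp = imu[0, ..., :3, :3], imu[1, ..., :3, :3], imu[2, ..., :3, :3]
        pm, pc, pp = imu[0, ..., :3, 3], imu[1, ..., :3, 3], imu[2, ..., :3, 3]
        accG = (pp - 2.0 * pc + pm) / h**2
        om = rotvec_from_matrix(np.einsum("mnji,mnjk->mnik", Rm, Rp)) / (2.0 * h)
        return accG, Rc, om

    def _residual_batch(self, X: np.ndarray, k: int, mag_mask):
        nz = self.config.noise
        accG, Rc, om = self._imu_prediction_batch(X)
        pred_a = np.einsum("mnji,mnj->mni", Rc, accG - self._g)
        M = X.shape[0]
        parts = [
            (self.data.acc[:, k][None] - pred_a).reshape(M, -1),
            (self.data.gyr[:, k][None] - om).reshape(M, -1),
        ]
        stds = [np.full(3 * self.n_seg, nz.sigma_acc), np.full(3 * self.n_seg, nz.sigma_gyro)]
        if self._use_mag:
            u = np.einsum("mnij,nj->mni", Rc, self._mag_unit(k))
            if mag_mask is None:
                mag_mask = np.hypot(u[0, :, 0], u[0, :, 1]) > MAG_HORIZONTAL_TOL
            parts.append(-np.arctan2(u[:, mag_mask, 1], u[:, mag_mask, 0]).reshape(M, -1))
            stds.append(np.full(int(mag_mask.sum()), nz.sigma_mag))
        return np.concatenate(parts, axis=1), np.concatenate(stds), mag_mask

    def _residual(self, mean, k: int, mag_mask=None):
        r, stds, mag_mask = self._residual_batch(self._state_vec(mean)[None, :], k, mag_mask)
        return r[0], stds, mag_mask

    def _measurement_H(self, mean, k: int, mag_mask) -> np.ndarray:
        eps = self.config.jacobian_step
        x0 = self._state_vec(mean)
        d = self.dim
        X = np.concatenate([x0[None, :] + eps * np.eye(d), x0[None, :] - eps * np.eye(d)])
        r, _, _ = self._residual_batch(X, k, mag_mask)
        J = (r[:d] - r[d:]).T / (2.0 * eps)
        return -J

    def _imu_quantities(self, s: _ChainState):
        accG, Rc, om = self.predict_imu_quantities(s.th, s.thd, s.thdd)
        q_GI = np.array([matrix_to_quat(Rc[i]) for i in range(self.n_seg)])
        return accG, q_GI, om

    def _segment_poses(self, s: _ChainState):
        seg, _ = chain_fk_matrices(self.model, s.th)
        q = np.array([matrix_to_quat(seg[i, :3, :3]) for i in range(self.n_seg)])
        return q, seg[:, :3, 3].copy()
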