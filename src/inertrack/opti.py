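"""Sliding-window weighted-least-squares tracker.

Each batch jointly estimates, for every time step of a window of length
``w``, the global pose (and velocity) of every IMU *and* the global pose of
every segment.  The window cost stacks, whitened by their noise levels:

* **calibration terms** tying each IMU pose to its segment pose through the
  I2S calibration (orientation and position mismatch) — modelling the
  calibration as uncertain rather than rigidly true;
* **motion-model terms** that strapdown-integrate the IMU data (gyroscope
  and accelerometer as control inputs) between consecutive window steps;
* **joint-connectivity terms** (soft constraints) and the **global anchor**;
* an optional low-weight **magnetometer heading** term;
* an **arrival term** penalizing jumps of the first window step's IMU
  orientations relative to the previous batch (TRIAD attitudes for the
  first batch).

The window slides with overlap ``ov`` (``w > ov >= 1``): ``ov = w-1`` is
moving-horizon (one new sample per solve), ``ov = 1`` advances ``w-1``
samples per solve.  Each time step's estimate is emitted exactly once, from
the last window that contains it before it leaves the overlap.

The nonlinear least-squares problems are solved by a damped Gauss-Newton
(Levenberg-Marquardt) iteration over an on-manifold local parametrization
(3-DoF multiplicative quaternion increments), with analytic block-sparse
Jacobians and a sparse normal-equations solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .body import BodyModel
from .ekf import initialize_orientations, place_segments_from_anchor
from .measurements import MAG_HORIZONTAL_TOL
from .quat import qconj, qexp, qlog, qmul, qnormalize, qrotate, quat_to_matrix, skew
from .results import TrackingResult
from .simulate import GRAVITY, IMUDataset

__all__ = ["OptiConfig", "WindowState", "Optitracker"]


@dataclass
class OptiConfig:
    """Window mechanics, residual weights and solver settings.

    Weights are standard deviations (whitening divides by them).  The
    calibration weights encode how much the I2S calibration is trusted;
    the magnetometer weight is deliberately weak.
    """

    window: int = 30
    overlap: int = 29
    use_magnetometer: bool = True
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    sigma_cq: float = 0.15  # rad, calibration orientation
    sigma_cp: float = 1.0  # m, calibration position (deliberately weak: the
    # I2S position is the least reliable model parameter, and a strong weight
    # would let position miscalibration distort the orientation estimates)
    sigma_phat: float = 1e-3  # m, position motion residual
    sigma_phatd: float = 5e-2  # m/s, velocity motion residual
    sigma_qhat: float = 1e-3  # rad, orientation motion residual
    sigma_anchor: float = 1e-3  # m
    sigma_mag: float = 0.5  # rad (low weight)
    sigma_q0: float = 0.01  # rad, arrival term (batch-to-batch continuity)
    sigma_q0_first: float = 0.5  # rad, weak anchor to the approximate initial attitude
    sigma_p: float = 1e-3  # m, joint constraints
    init_batch: int = 500  # first-batch length (samples); a longer free first
    # batch lets the optimizer correct the approximate initialization before
    # the sliding windows (which only maintain consistency) take over
    max_iterations: int = 25
    tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not (self.window > self.overlap >= 1):
            raise ValueError("require window > overlap >= 1")
        self.gravity = np.asarray(self.gravity, dtype=float).reshape(3)


@dataclass
class WindowState:
    """Batch state: per window step and segment, IMU pose+velocity and
    segment pose.  Shapes ``(w, n, .)``; ``batch`` is the batch number and
    ``start`` the absolute index of the first sample."""

    I: np.ndarray
    Id: np.ndarray
    qI: np.ndarray
    S: np.ndarray
    qS: np.ndarray
    batch: int = 0
    start: int = 0

    @property
    def w(self) -> int:
        return self.I.shape[0]

    @property
    def n(self) -> int:
        return self.I.shape[1]

    def copy(self) -> "WindowState":
        return WindowState(
            self.I.copy(), self.Id.copy(), self.qI.copy(), self.S.copy(), self.qS.copy(),
            self.batch, self.start,
        )

    def retract(self, delta: np.ndarray) -> "WindowState":
        """Apply a local increment: 15 numbers per (t, segment):
        ``[dI, dId, dthI, dS, dthS]``."""
        d = delta.reshape(self.w, self.n, 15)
        out = self.copy()
        out.I = self.I + d[..., 0:3]
        out.Id = self.Id + d[..., 3:6]
        out.qI = qnormalize(qmul(self.qI, qexp(0.5 * d[..., 6:9])))
        out.S = self.S + d[..., 9:12]
        out.qS = qnormalize(qmul(self.qS, qexp(0.5 * d[..., 12:15])))
        return out


def _jr_inv(a: np.ndarray) -> np.ndarray:
    """Inverse right Jacobian of SO(3) at rotation vector(s) ``a``.

    First-order corrections suffice for the small residual rotations that
    appear inside the window cost; the closed form is used anyway.
    """
    a = np.asarray(a, dtype=float)
    n = np.linalg.norm(a, axis=-1)
    Sa = skew(a)
    Sa2 = Sa @ Sa
    small = n < 1e-6
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.where(
            small,
            1.0 / 12.0,
            (1.0 / np.where(small, 1.0, n**2))
            - (1.0 + np.cos(n)) / np.where(small, 1.0, 2.0 * n * np.sin(n)),
        )
    eye = np.broadcast_to(np.eye(3), Sa.shape)
    return eye + 0.5 * Sa + coef[..., None, None] * Sa2


def _jl_inv(a: np.ndarray) -> np.ndarray:
    """Inverse left Jacobian: transpose of the inverse right Jacobian."""
    return np.swapaxes(_jr_inv(a), -1, -2)


class _COOBuilder:
    """Accumulates 3x3 (or 1x3) blocks of a sparse Jacobian."""

    def __init__(self) -> None:
        self.rows: list[np.ndarray] = []
        self.cols: list[np.ndarray] = []
        self.vals: list[np.ndarray] = []

    def add(self, row_base: np.ndarray, col_base: np.ndarray, blocks: np.ndarray) -> None:
        """``row_base``/``col_base``: (K,) first row/col of each block;
        ``blocks``: (K, r, c)."""
        K, r, c = blocks.shape
        rr = (row_base[:, None, None] + np.arange(r)[None, :, None]).repeat(c, axis=2)
        cc = (col_base[:, None, None] + np.arange(c)[None, None, :]).repeat(r, axis=1)
        self.rows.append(rr.ravel())
        self.cols.append(cc.ravel())
        self.vals.append(blocks.ravel())

    def build(self, shape: tuple[int, int]) -> sparse.csr_matrix:
        return sparse.coo_matrix(
            (np.concatenate(self.vals), (np.concatenate(self.rows), np.concatenate(self.cols))),
            shape=shape,
        ).tocsr()


class Optitracker:
    """Sliding-window optimizer over an :class:`IMUDataset` and body model."""

    method = "optitracker"

    def __init__(self, data: IMUDataset, model: BodyModel, config: OptiConfig | None = None):
        self.data = data
        self.model = model
        self.config = config or OptiConfig()
        self.T = data.sampling_time
        self.n_seg = model.n_segments
        if data.n_imus != model.n_segments:
            raise ValueError("dataset and model disagree on the number of IMUs")
        if data.n_samples < self.config.window:
            raise ValueError("dataset shorter than one window")
        self._use_mag = self.config.use_magnetometer and data.mag is not None
        self._q_SI = np.array([c.q_SI for c in model.calibrations])
        self._R_IS = quat_to_matrix(qconj(self._q_SI))
        self._r_IS = np.array([c.r_IS for c in model.calibrations])
        self._carry: np.ndarray | None = None

    # ------------------------------------------------------------------
    def _strapdown_step(self, I, Id, qI, k: int):
        """Propagate IMU states from sample ``k`` to ``k+1`` using the data."""
        T = self.T
        aG = qrotate(qI, self.data.acc[:, k]) + self.config.gravity
        return (
            I + T * Id + 0.5 * T**2 * aG,
            Id + T * aG,
            qnormalize(qmul(qI, qexp(0.5 * T * self.data.gyr[:, k]))),
        )

    def _segments_from_imus(self, qI: np.ndarray, I: np.ndarray):
        qS = qmul(qI, qconj(self._q_SI))
        S = I - qrotate(qS, self._r_IS)
        return qS, S

    def _initial_conditions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Initial IMU orientations, positions and velocities.

        Uses the shared dynamic chain-state initialization when the model
        has a DH table (removing the body-acceleration tilt bias of a plain
        first-sample TRIAD fix); TRIAD plus anchored placement otherwise.
        """
        if self.model.dh_table is not None and self.model.n_dofs:
            from .ekf import EKFConfig, chain_kinematics_snapshot, fit_initial_chain_state
            from .quat import matrix_to_quat

            ecfg = EKFConfig(use_magnetometer=self.config.use_magnetometer,
                             gravity=self.config.gravity)
            th, thd, thdd = fit_initial_chain_state(self.data, self.model, ecfg)
            kin = chain_kinematics_snapshot(self.model, th, thd, thdd)["imu"]
            q0 = np.array([matrix_to_quat(R) for R in kin["R"]])
            return q0, kin["p"], kin["v"]
        q0 = initialize_orientations(self.data, self.config)
        qS0 = qmul(q0, qconj(self._q_SI))
        S0 = place_segments_from_anchor(self.model, qS0)
        return q0, S0 + qrotate(qS0, self._r_IS), np.zeros((self.n_seg, 3))

    def _initial_window(self, q0: np.ndarray, I0: np.ndarray, Id0: np.ndarray,
                        w: int | None = None) -> WindowState:
        """First-batch guess: initial conditions then strapdown propagation."""
        n = self.n_seg
        w = self.config.window if w is None else w
        I = np.zeros((w, n, 3))
        Id = np.zeros((w, n, 3))
        qI = np.zeros((w, n, 4))
        I[0], Id[0], qI[0] = I0, Id0, q0
        for t in range(w - 1):
            I[t + 1], Id[t + 1], qI[t + 1] = self._strapdown_step(I[t], Id[t], qI[t], t)
        qS, S = self._segments_from_imus(qI, I)
        return WindowState(I, Id, qI, S, qS, batch=0, start=0)

    # ------------------------------------------------------------------
    # residual assembly (layout shared with the analytic Jacobian)
    def _mag_mask(self, st: WindowState) -> np.ndarray | None:
        if not self._use_mag:
            return None
        s0, w = st.start, st.w
        m = self.data.mag[:, s0 : s0 + w].transpose(1, 0, 2)
        u = qrotate(st.qI, m / np.linalg.norm(m, axis=-1, keepdims=True))
        return np.hypot(u[..., 0], u[..., 1]) > MAG_HORIZONTAL_TOL

    def _data_slice(self, st: WindowState):
        s0, w = st.start, st.w
        acc = self.data.acc[:, s0 : s0 + w].transpose(1, 0, 2)  # (w, n, 3)
        gyr = self.data.gyr[:, s0 : s0 + w].transpose(1, 0, 2)
        mag = None
        if self._use_mag:
            mag = self.data.mag[:, s0 : s0 + w].transpose(1, 0, 2)
            mag = mag / np.linalg.norm(mag, axis=-1, keepdims=True)
        return acc, gyr, mag

    def _residual_vector(self, st: WindowState, mag_mask: np.ndarray | None) -> np.ndarray:
        cfg = self.config
        w, n = st.w, st.n
        T = self.T
        acc, gyr, mag = self._data_slice(st)
        parts: list[np.ndarray] = []
        # calibration terms
        e_cq = 2.0 * qlog(qmul(qconj(self._q_SI), qmul(qconj(st.qS), st.qI)))
        e_cp = st.I - (st.S + qrotate(st.qS, self._r_IS))
        parts.append((e_cq / cfg.sigma_cq).ravel())
        parts.append((e_cp / cfg.sigma_cp).ravel())
        # motion model (control inputs: the data slice); trapezoidal
        # integration keeps the discretization error at O(T^3), consistent
        # with data obtained by central differencing
        aG = qrotate(st.qI, acc) + cfg.gravity
        e_p = st.I[1:] - (st.I[:-1] + T * st.Id[:-1] + T**2 / 6.0 * (2.0 * aG[:-1] + aG[1:]))
        e_v = st.Id[1:] - (st.Id[:-1] + 0.5 * T * (aG[:-1] + aG[1:]))
        e_q = 2.0 * qlog(
            qmul(qconj(st.qI[1:]), qmul(st.qI[:-1], qexp(0.25 * T * (gyr[:-1] + gyr[1:]))))
        )
        parts.append((e_p / cfg.sigma_phat).ravel())
        parts.append((e_v / cfg.sigma_phatd).ravel())
        parts.append((e_q / cfg.sigma_qhat).ravel())
        # anchor
        a = self.model.anchor
        e_G = st.S[:, a.segment] + qrotate(st.qS[:, a.segment], a.p_S) - a.P_G
        parts.append((e_G / cfg.sigma_anchor).ravel())
        # joints
        for j in self.model.joints:
            gap = (
                st.S[:, j.parent] + qrotate(st.qS[:, j.parent], self.model.endpoint(j.parent, j.parent_point))
            ) - (st.S[:, j.child] + qrotate(st.qS[:, j.child], self.model.endpoint(j.child, j.child_point)))
            parts.append((gap / cfg.sigma_p).ravel())
        # magnetometer heading
        if self._use_mag:
            u = qrotate(st.qI, mag)
            e_m = np.arctan2(u[..., 1], u[..., 0])
            if mag_mask is not None:
                e_m = np.where(mag_mask, e_m, 0.0)
            parts.append((e_m / cfg.sigma_mag).ravel())
        # arrival / initialization term (weak for the first batch, whose
        # carry is only the approximate initial attitude fit)
        sq0 = cfg.sigma_q0_first if st.batch == 0 else cfg.sigma_q0
        e_q0 = 2.0 * qlog(qmul(qconj(self._carry), st.qI[0]))
        parts.append((e_q0 / sq0).ravel())
        return np.concatenate(parts)

    def _jacobian(self, st: WindowState, mag_mask: np.ndarray | None) -> sparse.csr_matrix:
        """Analytic sparse Jacobian of the whitened residual stack."""
        cfg = self.config
        w, n = st.w, st.n
        T = self.T
        acc, gyr, mag = self._data_slice(st)
        nv = 15 * n * w

        def col(t_i_flat: np.ndarray, comp: int) -> np.ndarray:
            return 15 * t_i_flat + comp

        ti = np.arange(w * n)  # flat (t, i)
        ti_head = np.arange((w - 1) * n)  # (t, i) for t < w-1
        ti_next = ti_head + n
        B = _COOBuilder()
        eye = np.broadcast_to(np.eye(3), (w * n, 3, 3))
        eyeh = eye[: (w - 1) * n]
        row0 = 0
        # --- calibration orientation: e_cq = 2 log(qSI* qSG qI)
        e_cq = 2.0 * qlog(qmul(qconj(self._q_SI), qmul(qconj(st.qS), st.qI))).reshape(-1, 3)
        rb = row0 + 3 * ti
        B.add(rb, col(ti, 6), _jr_inv(e_cq) / cfg.sigma_cq)
        R_IS = np.broadcast_to(self._R_IS, (w, n, 3, 3)).reshape(-1, 3, 3)
        B.add(rb, col(ti, 12), -(_jl_inv(e_cq) @ R_IS) / cfg.sigma_cq)
        row0 += 3 * w * n
        # --- calibration position: e_cp = I - S - R_GS r
        R_GS = quat_to_matrix(st.qS).reshape(-1, 3, 3)
        rb = row0 + 3 * ti
        B.add(rb, col(ti, 0), eye / cfg.sigma_cp)
        B.add(rb, col(ti, 9), -eye / cfg.sigma_cp)
        lever = skew(np.broadcast_to(self._r_IS, (w, n, 3)).reshape(-1, 3))
        B.add(rb, col(ti, 12), (R_GS @ lever) / cfg.sigma_cp)
        row0 += 3 * w * n
        # --- motion position (trapezoidal; see _residual_vector)
        R_GI = quat_to_matrix(st.qI).reshape(w, n, 3, 3)
        RSy = R_GI @ skew(acc.reshape(w, n, 3))  # d(R y_a)/ddelta = -R S(y)
        RSy_t = RSy[:-1].reshape(-1, 3, 3)
        RSy_n = RSy[1:].reshape(-1, 3, 3)
        rb = row0 + 3 * ti_head
        B.add(rb, col(ti_next, 0), eyeh / cfg.sigma_phat)
        B.add(rb, col(ti_head, 0), -eyeh / cfg.sigma_phat)
        B.add(rb, col(ti_head, 3), -T * eyeh / cfg.sigma_phat)
        B.add(rb, col(ti_head, 6), (T**2 / 3.0 / cfg.sigma_phat) * RSy_t)
        B.add(rb, col(ti_next, 6), (T**2 / 6.0 / cfg.sigma_phat) * RSy_n)
        row0 += 3 * (w - 1) * n
        # --- motion velocity (trapezoidal)
        rb = row0 + 3 * ti_head
        B.add(rb, col(ti_next, 3), eyeh / cfg.sigma_phatd)
        B.add(rb, col(ti_head, 3), -eyeh / cfg.sigma_phatd)
        B.add(rb, col(ti_head, 6), (0.5 * T / cfg.sigma_phatd) * RSy_t)
        B.add(rb, col(ti_next, 6), (0.5 * T / cfg.sigma_phatd) * RSy_n)
        row0 += 3 * (w - 1) * n
        # --- motion orientation: e_q = 2 log(q'* q exp(T/4 (y_w + y_w')))
        u_mid = 0.25 * T * (gyr[:-1] + gyr[1:])
        e_q = 2.0 * qlog(
            qmul(qconj(st.qI[1:]), qmul(st.qI[:-1], qexp(u_mid)))
        ).reshape(-1, 3)
        R_u = quat_to_matrix(qexp(u_mid)).reshape(-1, 3, 3)
        rb = row0 + 3 * ti_head
        B.add(rb, col(ti_head, 6), (_jr_inv(e_q) @ np.swapaxes(R_u, -1, -2)) / cfg.sigma_qhat)
        B.add(rb, col(ti_next, 6), -_jl_inv(e_q) / cfg.sigma_qhat)
        row0 += 3 * (w - 1) * n
        # --- anchor
        a = self.model.anchor
        tt = np.arange(w)
        ti_a = tt * n + a.segment
        rb = row0 + 3 * tt
        eye_w = np.broadcast_to(np.eye(3), (w, 3, 3))
        B.add(rb, col(ti_a, 9), eye_w / cfg.sigma_anchor)
        Ra = quat_to_matrix(st.qS[:, a.segment])
        B.add(rb, col(ti_a, 12), -(Ra @ skew(np.broadcast_to(a.p_S, (w, 3)))) / cfg.sigma_anchor)
        row0 += 3 * w
        # --- joints
        for j in self.model.joints:
            for sgn, seg_i, which in ((1.0, j.parent, j.parent_point), (-1.0, j.child, j.child_point)):
                p = self.model.endpoint(seg_i, which)
                ti_j = tt * n + seg_i
                rb = row0 + 3 * tt
                B.add(rb, col(ti_j, 9), sgn * eye_w / cfg.sigma_p)
                Rj = quat_to_matrix(st.qS[:, seg_i])
                B.add(rb, col(ti_j, 12), -sgn * (Rj @ skew(np.broadcast_to(p, (w, 3)))) / cfg.sigma_p)
            row0 += 3 * w
        # --- magnetometer
        if self._use_mag:
            u = qrotate(st.qI, mag)
            den = u[..., 0] ** 2 + u[..., 1] ** 2
            gu = np.stack([-u[..., 1] / den, u[..., 0] / den, np.zeros_like(den)], axis=-1)
            rowvec = np.einsum("wnk,wnkl->wnl", gu, -(R_GI @ skew(mag)))
            if mag_mask is not None:
                rowvec = np.where(mag_mask[..., None], rowvec, 0.0)
            rb = row0 + ti
            B.add(rb, col(ti, 6), rowvec.reshape(-1, 1, 3) / cfg.sigma_mag)
            row0 += w * n
        # --- arrival term
        sq0 = cfg.sigma_q0_first if st.batch == 0 else cfg.sigma_q0
        e_q0 = 2.0 * qlog(qmul(qconj(self._carry), st.qI[0]))
        ii = np.arange(n)
        rb = row0 + 3 * ii
        B.add(rb, col(ii, 6), _jr_inv(e_q0) / sq0)
        row0 += 3 * n
        return B.build((row0, nv))

    # ------------------------------------------------------------------
    def assemble_cost(self, st: WindowState):
        """Stacked whitened residual vector and analytic sparse Jacobian."""
        mask = self._mag_mask(st)
        return self._residual_vector(st, mask), self._jacobian(st, mask)

    def solve_window(self, st: WindowState) -> tuple[WindowState, dict]:
        """Damped Gauss-Newton solve of one window."""
        cfg = self.config
        mask = self._mag_mask(st)
        r = self._residual_vector(st, mask)
        cost = 0.5 * float(r @ r)
        initial_cost = cost
        lam = 1e-10
        iters = 0
        converged = False
        for iters in range(1, cfg.max_iterations + 1):
            J = self._jacobian(st, mask)
            g = J.T @ r
            JtJ = (J.T @ J).tocsc()
            # Marquardt scaling with a damping floor: without a heading
            # reference the problem has an exact global-yaw null space, and
            # an undamped normal-equations solve would wander along it
            D = sparse.diags(JtJ.diagonal(), format="csc")
            accepted = False
            for _ in range(12):
                A = JtJ + max(lam, 1e-10) * D
                try:
                    delta = spsolve(A, -g)
                except RuntimeError:  # singular factorization: damp harder
                    lam = max(10.0 * lam, 1e-8)
                    continue
                st_new = st.retract(delta)
                r_new = self._residual_vector(st_new, mask)
                cost_new = 0.5 * float(r_new @ r_new)
                if np.isfinite(cost_new) and cost_new <= cost:
                    accepted = True
                    lam = lam / 3.0 if lam > 1e-12 else 0.0
                    break
                lam = max(10.0 * lam, 1e-6)
            if not accepted:
                break
            drop = cost - cost_new
            st, r, cost = st_new, r_new, cost_new
            if drop <= cfg.tolerance * max(1.0, cost):
                converged = True
                break
        diag = {
            "cost": cost,
            "initial_cost": initial_cost,
            "iterations": iters,
            "converged": converged or cost <= initial_cost,
        }
        return st, diag

    # ------------------------------------------------------------------
    def fit(self) -> TrackingResult:
        data = self.data
        cfg = self.config
        n_t, n, w = data.n_samples, self.n_seg, cfg.window
        q0, I0, Id0 = self._initial_conditions()
        self._carry = q0.copy()
        w0 = max(w, min(cfg.init_batch, n_t))
        st = self._initial_window(q0, I0, Id0, w=w0)
        seg_q = np.zeros((n, n_t, 4))
        seg_p = np.zeros((n, n_t, 3))
        imu_q = np.zeros((n, n_t, 4))
        imu_p = np.zeros((n, n_t, 3))
        costs: list[float] = []
        iters: list[int] = []
        emitted = 0
        batch = 0
        while True:
            st.batch = batch
            st, diag = self.solve_window(st)
            costs.append(diag["cost"])
            iters.append(diag["iterations"])
            last = st.start + st.w >= n_t
            # a step's estimate is final once its window is the last to hold it
            step = st.w - cfg.overlap
            upto = st.w if last else min(st.start + step, n_t - w) - st.start
            for t in range(emitted - st.start, upto):
                k = st.start + t
                seg_q[:, k] = st.qS[t]
                seg_p[:, k] = st.S[t]
                imu_q[:, k] = st.qI[t]
                imu_p[:, k] = st.I[t]
            emitted = st.start + upto
            if last:
                break
            # slide: keep the overlap, strapdown-propagate the new tail
            shift = upto
            new_start = st.start + shift
            self._carry = st.qI[shift].copy()
            I = np.empty((w, n, 3))
            Id = np.empty((w, n, 3))
            qI = np.empty((w, n, 4))
            keep = st.w - shift
            I[:keep], Id[:keep], qI[:keep] = st.I[shift:], st.Id[shift:], st.qI[shift:]
            for t in range(keep - 1, w - 1):
                I[t + 1], Id[t + 1], qI[t + 1] = self._strapdown_step(I[t], Id[t], qI[t], new_start + t)
            qS, S = self._segments_from_imus(qI, I)
            st = WindowState(I, Id, qI, S, qS, batch=batch + 1, start=new_start)
            batch += 1
        return TrackingResult(
            method=self.method,
            t=data.t.copy(),
            seg_quat=seg_q,
            seg_pos=seg_p,
            imu_quat=imu_q,
            imu_pos=imu_p,
            diagnostics={
                "window_costs": np.array(costs),
                "mean_iterations": float(np.mean(iters)),
                "n_windows": len(costs),
            },
            config=cfg,
        )
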