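import numpy as np
import pytest

import inertrack.ekf as ekf
from inertrack import EKFConfig, IMUDataset, angular_error_series, error_stats
from inertrack.ekf import (
    Chaintracker,
    QuattrackerIMU,
    QuattrackerSegment,
    chain_ik_init,
    chain_kinematics_snapshot,
    fit_initial_chain_state,
    initialize_orientations,
    place_segments_from_anchor,
)
from inertrack.body import chain_fk_matrices
from inertrack.quat import (
    matrix_to_quat,
    qconj,
    qexp,
    qmul,
    qrotate,
    random_quaternion,
    rotation_angle,
)
from inertrack.simulate import GRAVITY, animate_chain, trajectory_to_imu_data


def _static_dataset(arm_model, n=40):
    traj = animate_chain(arm_model, np.zeros((n, 9)))
    return trajectory_to_imu_data(traj), traj


class TestPredictModels:
    def test_quat_imu_rest_is_fixed_point(self, arm_model, study):
        trk = QuattrackerIMU(study[1], arm_model)
        mean, _ = trk._initialize()
        mean.v[:] = 0
        mean.a[:] = 0
        mean.w[:] = 0
        out = trk._predict_mean(mean)
        np.testing.assert_allclose(out.p, mean.p, atol=1e-15)
        np.testing.assert_allclose(out.q, mean.q, atol=1e-15)

    def test_quat_imu_closed_form_rotation(self, arm_model, study):
        trk = QuattrackerIMU(study[1], arm_model)
        trk.T = 0.5
        mean, _ = trk._initialize()
        q0 = mean.q.copy()
        mean.w[:] = [0, 0, np.pi]
        out = trk._predict_mean(mean)
        for i in range(3):
            delta = qmul(qconj(q0[i]), out.q[i])
            assert float(rotation_angle(delta, qexp(np.array([0, 0, np.pi / 4])))) < 1e-9

    def test_quat_seg_reduces_to_const_velocity(self, arm_model, study):
        seg = QuattrackerSegment(study[1], arm_model)
        imu = QuattrackerIMU(study[1], arm_model)
        ms, _ = seg._initialize()
        ms.wd[:] = 0
        ms.w[:] = np.array([0.3, -0.2, 0.5])
        out = seg._predict_mean(ms)
        expected = qmul(ms.q, qexp(0.5 * seg.T * ms.w))
        np.testing.assert_allclose(out.q, expected, atol=1e-12)

    def test_quat_seg_angular_acceleration_closed_form(self, arm_model, study):
        trk = QuattrackerSegment(study[1], arm_model)
        trk.T = 1.0
        mean, _ = trk._initialize()
        q0 = mean.q.copy()
        mean.w[:] = 0
        mean.wd[:] = [0, 0, np.pi]
        out = trk._predict_mean(mean)
        np.testing.assert_allclose(out.w, np.broadcast_to([0, 0, np.pi], (3, 3)), atol=1e-12)
        for i in range(3):
            delta = qmul(qconj(q0[i]), out.q[i])
            # increment exp(T/2 w + T^2/4 wd) -> 90 deg about z at T=1
            assert float(rotation_angle(delta, qexp(np.array([0, 0, np.pi / 4])))) < 1e-9

    def test_two_half_steps_match_full_step_to_second_order(self, arm_model, study, rng):
        trk = QuattrackerSegment(study[1], arm_model)
        mean, _ = trk._initialize()
        mean.w[:] = rng.standard_normal((3, 3))
        mean.wd[:] = rng.standard_normal((3, 3))
        trk.T = 0.02
        full = trk._predict_mean(mean)
        trk.T = 0.01
        half = trk._predict_mean(trk._predict_mean(mean))
        for i in range(3):
            assert float(rotation_angle(full.q[i], half.q[i])) < np.degrees(0.02**2)

    def test_chain_transition_exactly_linear(self, arm_model, study, rng):
        trk = Chaintracker(study[1], arm_model)
        mean, _ = trk._initialize()
        F, Q = trk._transition(mean)
        x0 = trk._state_vec(mean)
        d = rng.standard_normal(trk.dim)
        pert = trk._state_vec(trk._predict_mean(trk._boxplus(mean, d)))
        base = trk._state_vec(trk._predict_mean(mean))
        np.testing.assert_allclose(pert - base, F @ d, atol=1e-10)

    def test_covariance_grows_under_pure_prediction(self, arm_model, study):
        trk = QuattrackerIMU(study[1], arm_model)
        mean, P = trk._initialize()
        F, Q = trk._transition(mean)
        P2 = F @ P @ F.T + Q
        assert np.trace(P2) > np.trace(P)


class TestAccelerationTransport:
    def test_centripetal_closed_form(self, arm_model, study):
        trk = QuattrackerSegment(study[1], arm_model)
        mean, _ = trk._initialize()
        w = 3.0
        r = 0.3
        mean.Sdd[:] = 0
        mean.w[:] = [0, 0, w]
        mean.wd[:] = 0
        acc, _, _ = trk._imu_quantities(mean)
        for i, cal in enumerate(arm_model.calibrations):
            expected = -(w**2) * qrotate(mean.q[i], cal.r_IS * [1, 1, 0]) \
                if False else qrotate(mean.q[i], np.cross([0, 0, w], np.cross([0, 0, w], cal.r_IS)))
            np.testing.assert_allclose(acc[i], expected, atol=1e-12)

    def test_transport_matches_pose_differentiation(self, arm_model, study):
        """Rigid transport of acceleration agrees with finite differences of
        the IMU positions along a simulated trajectory."""
        truth, _ = study
        T = truth.sampling_time
        trk = QuattrackerSegment(study[1], arm_model)
        mean, _ = trk._initialize()
        errs = []
        for k in range(50, 550, 100):
            for i in range(3):
                # segment kinematics by central differences at sample k
                q = truth.seg_quat[i]
                p = truth.seg_pos[i]
                mean.q[i] = q[k]
                mean.S[i] = p[k]
                mean.Sdd[i] = (p[k + 1] - 2 * p[k] + p[k - 1]) / T**2
                from inertrack.quat import qlog

                w_mid = 2 * qlog(qmul(qconj(q[k - 1]), q[k + 1])) / (2 * T)
                mean.w[i] = w_mid
                w_a = 2 * qlog(qmul(qconj(q[k - 1]), q[k])) / T
                w_b = 2 * qlog(qmul(qconj(q[k]), q[k + 1])) / T
                mean.wd[i] = (w_b - w_a) / T
            acc, _, _ = trk._imu_quantities(mean)
            for i in range(3):
                pi = truth.imu_pos[i]
                fd = (pi[k + 1] - 2 * pi[k] + pi[k - 1]) / T**2
                errs.append(np.abs(acc[i] - fd).max())
        assert max(errs) < 0.05  # m/s^2: O(T^2) agreement at these rates


class TestChainMeasurementPrediction:
    def test_zero_rates(self, arm_model, study):
        trk = Chaintracker(study[1], arm_model)
        th = np.linspace(-0.4, 0.4, 9)
        acc, R, om = trk.predict_imu_quantities(th, np.zeros(9), np.zeros(9))
        np.testing.assert_allclose(om, 0, atol=1e-9)
        np.testing.assert_allclose(acc, 0, atol=1e-6)
        _, imu = chain_fk_matrices(arm_model, th)
        np.testing.assert_allclose(R, imu[:, :3, :3], atol=1e-12)

    def test_single_dof_spin_rate(self, arm_model, study):
        trk = Chaintracker(study[1], arm_model)
        thd = np.zeros(9)
        thd[2] = 2.5  # root theta DoF (about the root z axis)
        _, _, om = trk.predict_imu_quantities(np.zeros(9), thd, np.zeros(9))
        np.testing.assert_allclose(np.linalg.norm(om, axis=1), 2.5, atol=1e-6)

    def test_agrees_with_trajectory_differentiation(self, arm_model, study):
        """Chain measurement prediction matches central differences of the
        simulated IMU poses (the independent differentiation oracle)."""
        truth, data = study
        from inertrack.simulate import angle_sequence

        phi = angle_sequence()
        T = truth.sampling_time
        trk = Chaintracker(data, arm_model)
        for k in (100, 300, 500):
            th = np.full(9, phi[k])
            thd = np.full(9, (phi[k + 1] - phi[k - 1]) / (2 * T))
            thdd = np.full(9, (phi[k + 1] - 2 * phi[k] + phi[k - 1]) / T**2)
            acc, R, om = trk.predict_imu_quantities(th, thd, thdd)
            for i in range(3):
                # O(T^2) agreement between the virtual-step predictor and the
                # sampling-rate central differences of the data
                np.testing.assert_allclose(om[i], data.gyr[i, k], atol=0.02)
                pred_a = R[i].T @ (acc[i] - GRAVITY)
                np.testing.assert_allclose(pred_a, data.acc[i, k], atol=0.1)


class TestJacobians:
    @pytest.mark.parametrize("cls", [QuattrackerIMU, QuattrackerSegment])
    def test_analytic_H_matches_central_differences(self, cls, arm_model, study, rng):
        trk = cls(study[1], arm_model)
        mean, _ = trk._initialize()
        mean = trk._boxplus(mean, 0.2 * rng.standard_normal(trk.dim))
        _, _, mask = trk._residual(mean, 10)
        Ha = trk._measurement_H(mean, 10, mask)
        Hn = -trk._numeric_J(mean, 10, mask)
        scale = max(1.0, np.abs(Hn).max())
        assert np.abs(Ha - Hn).max() / scale < 1e-5


class TestUpdateContracts:
    def test_measurement_stack_sizes(self, arm_model, study):
        _, data = study
        trk = QuattrackerIMU(data, arm_model, EKFConfig(use_magnetometer=True))
        mean, _ = trk._initialize()
        r, std, _ = trk._residual(mean, 0)
        # 7 rows per IMU + 3 per joint + 3 anchor
        assert r.shape[0] == 7 * 3 + 3 * 2 + 3
        trk = QuattrackerIMU(data, arm_model, EKFConfig(use_magnetometer=False))
        r, std, _ = trk._residual(mean, 0)
        assert r.shape[0] == 6 * 3 + 3 * 2 + 3

    def test_zero_residual_leaves_mean_contracts_covariance(self, arm_model, study):
        trk = QuattrackerIMU(study[1], arm_model)
        mean, P = trk._initialize()
        r, std, mask = trk._residual(mean, 0)
        H = trk._measurement_H(mean, 0, mask)
        # synthetic exactly-consistent measurement: force r = 0
        S = H @ P @ H.T + np.diag(std**2)
        K = np.linalg.solve(S, H @ P).T
        delta = K @ np.zeros_like(r)
        np.testing.assert_allclose(delta, 0, atol=1e-15)
        IKH = np.eye(trk.dim) - K @ H
        P2 = IKH @ P @ IKH.T + (K * std**2) @ K.T
        assert np.trace(P2) < np.trace(P)

    def test_disconnected_joints_pulled_together(self, arm_model, study):
        trk = QuattrackerSegment(study[1], arm_model)
        mean, P = trk._initialize()
        mean.S[2] += np.array([0.05, 0, 0])  # break a joint
        r0, _, mask = trk._residual(mean, 0)
        gap0 = np.linalg.norm(r0[-6:-3])
        mean2, P2, _ = trk._update(mean, P, 0)
        r1, _, _ = trk._residual(mean2, 0, mask)
        assert np.linalg.norm(r1[-6:-3]) < gap0


class TestInitialization:
    def test_static_init_matches_truth(self, arm_model):
        data, traj = _static_dataset(arm_model)
        for cls in (QuattrackerIMU, QuattrackerSegment, Chaintracker):
            trk = cls(data, arm_model)
            mean, _ = trk._initialize()
            q, p = trk._segment_poses(mean)
            for i in range(3):
                assert float(rotation_angle(q[i], traj.seg_quat[i, 0])) < 0.1

    def test_dynamic_init_on_moving_sequence(self, arm_model, study):
        truth, data = study
        th, thd, thdd = fit_initial_chain_state(data, arm_model, EKFConfig())
        kin = chain_kinematics_snapshot(arm_model, th, thd, thdd)["seg"]
        for i in range(3):
            q = matrix_to_quat(kin["R"][i])
            assert float(rotation_angle(q, truth.seg_quat[i, 0])) < 0.5

    def test_joint_constraints_satisfied_at_init(self, arm_model, study):
        trk = QuattrackerIMU(study[1], arm_model)
        mean, _ = trk._initialize()
        r, _, _ = trk._residual(mean, 0)
        assert np.abs(r[-9:]).max() < 1e-6  # joint + anchor rows

    def test_anchored_placement_exact(self, arm_model, rng):
        q = random_quaternion(rng, 3)
        pos = place_segments_from_anchor(arm_model, q)
        a = arm_model.anchor
        np.testing.assert_allclose(pos[a.segment] + qrotate(q[a.segment], a.p_S), a.P_G, atol=1e-12)
        for j in arm_model.joints:
            pp = pos[j.parent] + qrotate(q[j.parent], arm_model.endpoint(j.parent, "dist"))
            cc = pos[j.child] + qrotate(q[j.child], arm_model.endpoint(j.child, "prox"))
            np.testing.assert_allclose(pp, cc, atol=1e-12)

    def test_ik_objective_not_worse_than_zero_angles(self, arm_model, study):
        _, data = study
        q_GI = initialize_orientations(data, EKFConfig())
        th = chain_ik_init(arm_model, q_GI)

        def objective(x):
            _, imu = chain_fk_matrices(arm_model, x)
            total = 0.0
            for i in range(3):
                q_fk = matrix_to_quat(imu[i, :3, :3])
                total += float(rotation_angle(q_fk, q_GI[i])) ** 2
            return total

        assert objective(th) <= objective(np.zeros(9)) + 1e-9


class TestTrackingRuns:
    @pytest.mark.parametrize("cls", [Chaintracker, QuattrackerSegment, QuattrackerIMU])
    def test_static_data_static_estimates(self, cls, arm_model):
        data, traj = _static_dataset(arm_model)
        res = cls(data, arm_model).fit()
        err = angular_error_series(res.seg_quat, traj.seg_quat)
        assert err.max() < 0.1
        # estimates stay constant over time
        drift = angular_error_series(res.seg_quat[:, 1:], res.seg_quat[:, :-1])
        assert drift.max() < 0.05

    def test_covariance_stays_psd_and_quats_unit(self, arm_model, short_study):
        truth, data = short_study
        res = QuattrackerSegment(data, arm_model).fit()
        np.testing.assert_allclose(np.linalg.norm(res.seg_quat, axis=-1), 1.0, atol=1e-9)

    def test_short_run_regression(self, arm_model, short_study):
        truth, data = short_study
        for cls, bound in ((Chaintracker, 0.5), (QuattrackerSegment, 1.5), (QuattrackerIMU, 3.0)):
            res = cls(data, arm_model).fit()
            st = error_stats(angular_error_series(res.seg_quat, truth.seg_quat))
            assert st.e_mean < bound, cls.__name__

    def test_summary_reports_errors(self, arm_model, short_study):
        truth, data = short_study
        res = Chaintracker(data, arm_model).fit()
        text = res.summary(truth.seg_quat)
        assert "chaintracker" in text
        assert "angular error" in text
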