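"""Rigid-body dynamics, contact model and integrator."""

import dataclasses

import numpy as np
import pytest

from synergait import _engine
from synergait.skeleton_dynamics import (
    BodyParameters,
    SkeletonState,
    contact_forces,
    equations_of_motion,
    initial_state,
    joint_passive_torques,
    kinematics,
    mass_matrix,
    rk4_step,
    segment_coms,
    total_energy,
    whole_body_com,
)


def _passive_body(body):
    return dataclasses.replace(
        body, c_hip=0.0, c_knee=0.0, c_ankle=0.0, k_limit=0.0, c_limit=0.0
    )


class TestKinematics:
    def test_reference_pose_geometry(self, body):
        q = np.zeros(9)
        q[1] = body.standing_height
        kin = kinematics(SkeletonState(q=q), body)
        # straight vertical legs: knees/ankles stacked under the hip at x=0
        np.testing.assert_allclose(kin["hip"], [0.0, q[1] - body.d_hip], atol=1e-12)
        for leg in ("r", "l"):
            assert kin[f"knee_{leg}"][0] == pytest.approx(0.0, abs=1e-12)
            assert kin[f"ankle_{leg}"][0] == pytest.approx(0.0, abs=1e-12)
            assert kin[f"ankle_{leg}"][1] == pytest.approx(body.h_sole, abs=1e-12)
        # sole points sit on the ground plane
        np.testing.assert_allclose(kin["sole_pos"][:, :, 1], 0.0, atol=1e-12)

    def test_symmetric_pose_com_on_trunk_axis(self, body):
        q = np.zeros(9)
        q[3:6] = [0.3, 0.5, -0.1]
        q[6:9] = [0.3, 0.5, -0.1]
        com = whole_body_com(q, body)
        # both legs identical: COM x equals the (vertical-trunk) x of leg COMs mean; trunk at x=0
        com_mirror = whole_body_com(q * np.array([1, 1, 1, 1, 1, 1, 1, 1, 1]), body)
        np.testing.assert_allclose(com, com_mirror)
        coms, masses = segment_coms(q, body)
        assert coms.shape == (7, 2) and masses.sum() == pytest.approx(body.total_mass)

    def test_contact_point_velocity_matches_finite_difference(self, body):
        rng = np.random.default_rng(1)
        q = rng.uniform(-0.5, 0.5, 9)
        qd = rng.uniform(-1, 1, 9)
        eps = 1e-7
        _, _, sp0, sv0, _ = _engine.kin_eom(q, qd, body.packed())
        _, _, sp1, _, _ = _engine.kin_eom(q + eps * qd, qd, body.packed())
        fd = (np.asarray(sp1) - np.asarray(sp0)) / eps
        np.testing.assert_allclose(np.asarray(sv0), fd, atol=1e-5)

    def test_sole_jacobian_consistent_with_positions(self, body):
        rng = np.random.default_rng(2)
        q = rng.uniform(-0.5, 0.5, 9)
        _, _, sp0, _, sJ = _engine.kin_eom(q, np.zeros(9), body.packed())
        eps = 1e-7
        for j in range(9):
            dq = np.zeros(9)
            dq[j] = eps
            _, _, sp1, _, _ = _engine.kin_eom(q + dq, np.zeros(9), body.packed())
            fd = (np.asarray(sp1) - np.asarray(sp0)) / eps
            np.testing.assert_allclose(np.asarray(sJ)[:, :, :, j], fd, atol=1e-5)


class TestEquationsOfMotion:
    def test_free_fall(self, body):
        q = np.zeros(9)
        q[1] = 3.0
        q[3:] = [0.3, 0.4, -0.1, 0.3, 0.4, -0.1]
        qdd = equations_of_motion(
            SkeletonState(q=q), np.zeros(6), np.zeros((2, 4, 2)), _passive_body(body)
        )
        np.testing.assert_allclose(qdd, [0, -body.g, 0, 0, 0, 0, 0, 0, 0], atol=1e-9)

    def test_free_fall_has_no_relative_joint_motion(self, body):
        # airborne and unforced, every joint acceleration vanishes regardless
        # of posture (gravity cannot drive relative motion in free fall)
        rng = np.random.default_rng(3)
        for _ in range(5):
            q = rng.uniform(-0.8, 0.8, 9)
            q[1] = 5.0
            qdd = equations_of_motion(
                SkeletonState(q=q), np.zeros(6), np.zeros((2, 4, 2)),
                _passive_body(body),
            )
            np.testing.assert_allclose(qdd[2:], 0.0, atol=1e-8)
            assert qdd[1] == pytest.approx(-body.g)

    def test_hip_torque_pendulum_inertia(self, body):
        # gravity off, trunk made overwhelmingly heavy, distal segments light:
        # a hip torque accelerates the thigh like a rigid pendulum about a
        # fixed pivot, qdd = tau / (I + m c^2)
        b = dataclasses.replace(
            _passive_body(body), g=0.0,
            m_trunk=1e5, i_trunk=1e5,
            m_shank=1e-5, i_shank=1e-5, m_foot=1e-5, i_foot=1e-5,
        )
        q = np.zeros(9)
        q[1] = 3.0
        q[3] = 0.4
        tau = np.zeros(6)
        tau[0] = 5.0
        qdd = equations_of_motion(SkeletonState(q=q), tau, np.zeros((2, 4, 2)), b)
        expect = 5.0 / (b.i_thigh + b.m_thigh * b.c_thigh**2)
        assert qdd[3] == pytest.approx(expect, rel=1e-3)

    def test_matches_lagrangian_oracle(self, body, lagrangian_oracle):
        pb = _passive_body(body)
        rng = np.random.default_rng(11)
        for _ in range(100):
            q = rng.uniform(-1, 1, 9)
            qd = rng.uniform(-2, 2, 9)
            Mo, ho = lagrangian_oracle(q, qd)
            qdd_o = np.linalg.solve(Mo, ho)
            qdd = equations_of_motion(
                SkeletonState(q=q, qd=qd), np.zeros(6), np.zeros((2, 4, 2)), pb
            )
            scale = max(1.0, np.max(np.abs(qdd_o)))
            assert np.max(np.abs(qdd - qdd_o)) / scale < 1e-6

    def test_mass_matrix_spd(self, body):
        rng = np.random.default_rng(7)
        for _ in range(25):
            M = mass_matrix(rng.uniform(-np.pi / 2, np.pi / 2, 9), body)
            np.testing.assert_allclose(M, M.T, atol=1e-10)
            assert np.min(np.linalg.eigvalsh(M)) > 0.0

    def test_singular_body_rejected(self, body):
        bad = dataclasses.replace(body, m_trunk=0.0, i_trunk=0.0)
        with pytest.raises(ValueError):
            equations_of_motion(
                SkeletonState(q=np.zeros(9)), np.zeros(6), np.zeros((2, 4, 2)),
                dataclasses.replace(bad, m_thigh=0.0, i_thigh=0.0,
                                    m_shank=0.0, i_shank=0.0, m_foot=0.0, i_foot=0.0),
            )


class TestContact:
    def test_point_above_ground_is_free(self, body):
        q = np.zeros(9)
        q[1] = body.standing_height + 0.5
        out = contact_forces(SkeletonState(q=q), body)
        np.testing.assert_allclose(out["point_forces"], 0.0)

    def test_static_penetration_spring_force(self, body):
        delta = 0.003
        q = np.zeros(9)
        q[1] = body.standing_height - delta
        out = contact_forces(SkeletonState(q=q), body)
        np.testing.assert_allclose(
            out["point_forces"][:, :, 1], body.k_contact * delta, rtol=1e-9
        )
        # standing weight is carried with < 5 mm penetration
        w = body.total_mass * body.g
        assert w / (8 * body.k_contact) < 0.005

    def test_never_adhesive(self, body):
        # rapid upward withdrawal: damping would exceed the spring force
        q = np.zeros(9)
        q[1] = body.standing_height - 0.001
        qd = np.zeros(9)
        qd[1] = 5.0
        out = contact_forces(SkeletonState(q=q, qd=qd), body)
        assert np.all(out["point_forces"][:, :, 1] >= 0.0)

    def test_anchor_slip_respects_friction_cone(self, body):
        bp = body.packed()
        q = np.zeros(9)
        q[1] = body.standing_height - 0.002
        _, _, sp, sv, _ = _engine.kin_eom(q, np.zeros(9), bp)
        sp = np.asarray(sp)
        sv = np.asarray(sv)
        anchors = sp[:, :, 0] - 1.0  # absurdly stretched anchor
        active = np.ones((2, 4), dtype=np.int64)
        f = np.asarray(_engine.contact_forces(sp, sv, anchors, active, bp))
        assert np.all(np.abs(f[:, :, 0]) <= body.mu * f[:, :, 1] + 1e-9)
        _engine.update_anchors(sp, sv, anchors, active, bp)
        f2 = np.asarray(_engine.contact_forces(sp, sv, anchors, active, bp))
        np.testing.assert_allclose(
            np.abs(f2[:, :, 0]), body.mu * f2[:, :, 1], rtol=1e-9
        )


class TestPassiveJointTorques:
    def test_static_within_limits_is_free(self, body):
        q = np.zeros(9)
        q[4] = q[7] = 1.0  # knees well inside [0.1, 2.8]
        tau = joint_passive_torques(SkeletonState(q=q), body)
        np.testing.assert_allclose(tau, 0.0)

    def test_linear_viscosity(self, body):
        qd = np.zeros(9)
        qd[3] = 2.0
        q = np.zeros(9)
        q[4] = 1.0
        tau = joint_passive_torques(SkeletonState(q=q, qd=qd), body)
        assert tau[0] == pytest.approx(-body.c_hip * 2.0)

    def test_knee_limit_restoring(self, body):
        q = np.zeros(9)
        q[4] = 2.9  # beyond the 2.8 rad knee limit
        tau = joint_passive_torques(SkeletonState(q=q), body)
        assert tau[1] == pytest.approx(-body.k_limit * 0.1, rel=1e-9)
        q[4] = 0.0  # beyond the 0.1 rad lower limit
        tau = joint_passive_torques(SkeletonState(q=q), body)
        assert tau[1] == pytest.approx(body.k_limit * 0.1, rel=1e-9)


class TestRK4:
    def test_constant_rate_exact(self):
        y = rk4_step(np.array([2.0]), 0.25, lambda y: np.array([1.0]))
        assert y[0] == pytest.approx(2.25, abs=1e-15)

    def test_fourth_order_convergence_on_exponential(self):
        # one step of ydot = y: error vs e^dt shrinks ~16x per dt halving
        errs = []
        for dt in (0.1, 0.05, 0.025):
            y = rk4_step(np.array([1.0]), dt, lambda y: y)
            errs.append(abs(y[0] - np.exp(dt)))
        assert errs[0] / errs[1] == pytest.approx(2**5, rel=0.2)
        assert errs[1] / errs[2] == pytest.approx(2**5, rel=0.2)

    def test_nonfinite_state_aborts(self):
        with pytest.raises(FloatingPointError):
            rk4_step(np.array([1.0]), 1.0, lambda y: np.array([np.inf]))
        with pytest.raises(ValueError):
            rk4_step(np.array([1.0]), 0.0, lambda y: y)


class TestEnergy:
    def test_conserved_when_passive_and_airborne(self, body):
        pb = _passive_body(body)
        rng = np.random.default_rng(0)
        q = rng.uniform(-0.3, 0.3, 9)
        q[1] = 5.0
        qd = rng.uniform(-0.5, 0.5, 9)
        y = np.concatenate([q, qd])

        def f(y):
            qdd = equations_of_motion(
                SkeletonState(q=y[:9], qd=y[9:]), np.zeros(6), np.zeros((2, 4, 2)), pb
            )
            return np.concatenate([y[9:], qdd])

        E0 = total_energy(SkeletonState(q=q, qd=qd), pb)
        for _ in range(2000):  # 0.1 s at the smoke step
            y = rk4_step(y, 5e-5, f)
        E1 = total_energy(SkeletonState(q=y[:9], qd=y[9:]), pb)
        assert abs(E1 - E0) / abs(E0) < 1e-8

    def test_viscosity_dissipates(self, body):
        pb = dataclasses.replace(body, k_limit=0.0, c_limit=0.0)
        q = np.zeros(9)
        q[1] = 5.0
        qd = np.zeros(9)
        qd[3:] = [2.0, -1.0, 1.0, -2.0, 1.0, -1.0]
        y = np.concatenate([q, qd])

        def f(y):
            st = SkeletonState(q=y[:9], qd=y[9:])
            tau = joint_passive_torques(st, pb)
            qdd = equations_of_motion(st, tau, np.zeros((2, 4, 2)), pb)
            return np.concatenate([y[9:], qdd])

        energies = [total_energy(SkeletonState(q=q, qd=qd), pb)]
        for k in range(400):
            y = rk4_step(y, 1e-4, f)
            if k % 40 == 39:
                energies.append(total_energy(SkeletonState(q=y[:9], qd=y[9:]), pb))
        assert all(e1 <= e0 + 1e-10 for e0, e1 in zip(energies, energies[1:]))
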