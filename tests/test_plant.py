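"""Plant tests: ligament law, contact, torque aggregation, dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurogait.muscle import DEFAULT_MUSCLES
from neurogait.plant import (DEFAULT_JOINTS, Biped, ContactModel, PlantState,
                             aggregate_joint_torques, contact_force,
                             grf_normalized, ligament_torque,
                             soft_limit_torque)

FLAT = np.array([[-100.0, 0.0], [100.0, 0.0]])


class TestLigament:
    def test_inside_range_is_zero(self):
        for omega in (-5.0, 0.0, 5.0):
            assert soft_limit_torque(0.0, omega) == 0.0
            assert soft_limit_torque(-0.3, omega) == 0.0

    def test_fast_retraction_is_zero(self):
        # omega/omega_ref = -1.5: retracting faster than the reference
        assert soft_limit_torque(0.2, -1.5 * 1.74e-2) == 0.0

    def test_unit_overshoot_at_rest(self):
        assert soft_limit_torque(1.0, 0.0) == pytest.approx(17.19)

    def test_continuous_at_zero_overshoot(self):
        assert soft_limit_torque(1e-12, 0.0) == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5))
    @settings(deadline=None, max_examples=200)
    def test_zero_set_property(self, dphi, omega):
        tau = soft_limit_torque(dphi, omega)
        if dphi <= 0 or omega / 1.74e-2 <= -1:
            assert tau == 0.0
        else:
            assert tau >= 0.0

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            soft_limit_torque(math.nan, 0.0)

    def test_joint_torque_opposes_overtravel(self):
        knee = DEFAULT_JOINTS["knee"]
        # past the upper limit: restoring torque is negative (pushes back)
        assert ligament_torque(knee.phi_max + 0.1, 0.0, knee) < 0
        # past the lower limit: restoring torque is positive
        assert ligament_torque(knee.phi_min - 0.1, 0.0, knee) > 0
        # inside: zero
        assert ligament_torque(0.5 * (knee.phi_min + knee.phi_max), 1.0, knee) == 0.0

    def test_approach_speed_stiffens_response(self):
        knee = DEFAULT_JOINTS["knee"]
        slow = abs(ligament_torque(knee.phi_max + 0.1, 0.0, knee))
        fast = abs(ligament_torque(knee.phi_max + 0.1, 0.5, knee))
        assert fast > slow


class TestContact:
    def test_no_force_above_ground(self):
        f, _ = contact_force(np.array([0.0, 0.1]), np.zeros(2), 0.0,
                             FLAT, ContactModel())
        assert np.all(f == 0.0)

    def test_static_penetration_spring_value(self):
        m = ContactModel()
        delta = 0.004
        f, _ = contact_force(np.array([0.0, -delta]), np.zeros(2), 0.0,
                             FLAT, m)
        assert f[1] == pytest.approx(m.k_z * delta)
        assert f[0] == 0.0

    def test_fast_retraction_never_pulls(self):
        m = ContactModel()
        f, _ = contact_force(np.array([0.0, -0.004]),
                             np.array([0.0, 10 * m.v_ref]), 0.0, FLAT, m)
        assert f[1] >= 0.0

    def test_continuous_at_zero_depth(self):
        m = ContactModel()
        f, _ = contact_force(np.array([0.0, -1e-9]), np.zeros(2), 0.0,
                             FLAT, m)
        assert f[1] == pytest.approx(0.0, abs=1e-3)

    def test_friction_cone_bounds_horizontal_force(self):
        m = ContactModel()
        f, _ = contact_force(np.array([0.5, -0.003]), np.array([1.0, 0.0]),
                             0.0, FLAT, m)
        assert abs(f[0]) <= m.mu * f[1] + 1e-9


class TestGrf:
    def test_zero_forces(self):
        assert grf_normalized(0.0, 0.0, 800.0) == 0.0

    def test_arithmetic(self):
        assert grf_normalized(300.0, 500.0, 800.0) == pytest.approx(1.0)

    def test_rejects_bad_weight(self):
        with pytest.raises(ValueError):
            grf_normalized(1.0, 1.0, 0.0)

    def test_static_stance_supports_body_weight(self):
        """Standing at rest the two feet together carry one body weight."""
        biped = Biped(ground=FLAT)
        state = biped.standing_state()
        # settle briefly (contact spring finds equilibrium penetration)
        for _ in range(400):
            state = biped.step_dynamics(state, np.zeros(9), None, 1e-3)
        total = biped.foot_grf(state).sum()
        assert total == pytest.approx(1.0, rel=0.05)


class TestTorqueAggregation:
    ANGLES = {"hip": math.pi, "knee": math.pi, "ankle": math.pi / 2}

    def test_zero_forces_zero_torques(self):
        tau = aggregate_joint_torques({p.name: 0.0 for p in DEFAULT_MUSCLES},
                                      self.ANGLES, DEFAULT_MUSCLES)
        assert all(v == 0.0 for v in tau.values())

    def test_uniarticular_single_joint(self):
        tau = aggregate_joint_torques({"GLU": 100.0}, self.ANGLES,
                                      DEFAULT_MUSCLES)
        assert tau["hip"] == pytest.approx(100.0 * 0.10)
        assert tau["knee"] == 0.0 and tau["ankle"] == 0.0

    def test_biarticular_ham_spans_hip_and_knee(self):
        # HAM extends the hip and flexes the knee with the table's arm
        tau = aggregate_joint_torques({"HAM": 100.0}, self.ANGLES,
                                      DEFAULT_MUSCLES)
        assert tau["hip"] == pytest.approx(100.0 * 0.08)
        knee_arm = 0.08 * math.cos(math.pi - math.pi)  # phi = phi_max = 180
        assert tau["knee"] == pytest.approx(-100.0 * knee_arm)
        assert tau["ankle"] == 0.0

    def test_linear_in_forces(self):
        t1 = aggregate_joint_torques({"GAS": 50.0}, self.ANGLES, DEFAULT_MUSCLES)
        t2 = aggregate_joint_torques({"GAS": 100.0}, self.ANGLES, DEFAULT_MUSCLES)
        for j in t1:
            assert t2[j] == pytest.approx(2 * t1[j])

    def test_unknown_muscle_rejected(self):
        with pytest.raises(KeyError):
            aggregate_joint_torques({"XYZ": 1.0}, self.ANGLES, DEFAULT_MUSCLES)


class TestDynamics:
    def test_passive_chain_conserves_energy(self):
        """A passive airborne double-pendulum configuration drifts less
        than 0.1% in total mechanical energy over one second of RK4."""
        biped = Biped(ground=FLAT)
        q = biped.standing_state().q.copy()
        q[1] += 2.0  # airborne, no contact
        q[3], q[4], q[6] = 0.7, -0.4, -0.5
        state = PlantState(q, np.zeros(9))
        e0 = biped.total_energy(state)
        for _ in range(1000):
            state = biped.step_dynamics(state, np.zeros(9), None, 1e-3,
                                        with_contact=False)
        e1 = biped.total_energy(state)
        assert abs(e1 - e0) / abs(e0) < 1e-3

    def test_static_support_stays_put(self):
        """A statically supported pose at rest barely moves over 0.1 s.

        The equilibrium is only neutral (soft contact, passive joints,
        an inverted-pendulum trunk), so 'unchanged' means within a few
        milliradians over a short window after contact settling."""
        biped = Biped(ground=FLAT)
        state = biped.standing_state()
        for _ in range(200):
            state = biped.step_dynamics(state, np.zeros(9), None, 1e-3)
        q0 = state.q.copy()
        for _ in range(100):
            state = biped.step_dynamics(state, np.zeros(9), None, 1e-3)
        assert np.allclose(state.q, q0, atol=5e-3)

    def test_small_oscillation_period_matches_pendulum(self):
        """A massive thigh swinging from a quasi-inertial hip recovers
        the physical-pendulum closed-form period within 0.5%.

        The trunk is made very heavy (the hip barely moves), distal
        segments nearly massless, so the thigh is a 1-DoF physical
        pendulum: T = 2 pi sqrt((I + m d^2)/(m g d))."""
        from neurogait.plant import SegmentParams
        segments = {
            "trunk": SegmentParams("trunk", 1e5, 0.8, 0.35, 1e5),
            "thigh": SegmentParams("thigh", 8.5, 0.5, 0.30, 0.15),
            "shank": SegmentParams("shank", 1e-3, 0.5, 0.30, 1e-6),
            "foot": SegmentParams("foot", 1e-3, 0.2, 0.05, 1e-7),
        }
        biped = Biped(segments=segments, ground=FLAT)
        m, d, i_com = 8.5, 0.30, 0.15
        t_expected = 2 * math.pi * math.sqrt((i_com + m * d * d) / (m * 9.81 * d))
        q = biped.standing_state().q.copy()
        q[1] += 5.0  # airborne: no contact
        theta0 = 0.05
        q[3] = theta0  # displace the left hip; legs otherwise hang straight
        q[6] = 0.0
        state = PlantState(q, np.zeros(9))
        # support the heavy trunk against gravity so the hip is a
        # quasi-inertial pivot rather than in free fall
        support = [(0, np.array([0.0, 9.81 * biped.total_mass]))]
        crossings = []
        prev = theta0
        t = 0.0
        for _ in range(4000):
            state = biped.step_dynamics(state, np.zeros(9), support, 1e-3,
                                        with_contact=False)
            t += 1e-3
            cur = state.q[3]
            if prev < 0 <= cur:
                crossings.append(t)
            prev = cur
        assert len(crossings) >= 2
        period = float(np.mean(np.diff(crossings)))
        assert period == pytest.approx(t_expected, rel=5e-3)

    def test_free_flight_com_is_ballistic(self):
        """With no contact or torques, the COM follows the closed-form
        projectile parabola regardless of internal joint motion."""
        biped = Biped(ground=FLAT)
        q = biped.standing_state().q.copy()
        q[1] += 5.0
        q[3], q[4], q[6] = 0.8, -0.5, -0.6
        qd = np.zeros(9)
        qd[0], qd[1], qd[3], qd[7] = 1.0, 2.0, 3.0, -2.0
        state = PlantState(q, qd)
        com0 = biped.com(state)
        kin = biped.kinematics(state.q, state.qd)
        v0 = (biped.masses[:, None] * kin["com_vel"]).sum(axis=0) / biped.total_mass
        t_tot = 0.5
        for _ in range(500):
            state = biped.step_dynamics(state, np.zeros(9), None, 1e-3,
                                        with_contact=False)
        com1 = biped.com(state)
        expected = com0 + v0 * t_tot + 0.5 * np.array([0.0, -9.81]) * t_tot ** 2
        assert np.allclose(com1, expected, atol=1e-8)

    def test_left_right_mirror_symmetry(self):
        """Mirroring the joint state mirrors the accelerations exactly."""
        biped = Biped(ground=FLAT)
        q = biped.standing_state().q.copy()
        qd = np.zeros(9)
        q[3], q[4], q[5] = 0.3, -0.2, 0.1
        qd[3], qd[4] = 1.0, -0.5
        tau = np.zeros(9)
        tau[3], tau[4] = 10.0, -5.0
        acc = biped.accel(q, qd, tau, with_contact=False)
        qm, qdm, taum = q.copy(), qd.copy(), tau.copy()
        qm[3:6], qm[6:9] = q[6:9], q[3:6]
        qdm[3:6], qdm[6:9] = qd[6:9], qd[3:6]
        taum[3:6], taum[6:9] = tau[6:9], tau[3:6]
        accm = biped.accel(qm, qdm, taum, with_contact=False)
        assert np.allclose(acc[:3], accm[:3], atol=1e-10)
        assert np.allclose(acc[3:6], accm[6:9], atol=1e-10)
        assert np.allclose(acc[6:9], accm[3:6], atol=1e-10)

    def test_nonfinite_torque_rejected(self):
        biped = Biped(ground=FLAT)
        state = biped.standing_state()
        with pytest.raises(ValueError):
            biped.step_dynamics(state, np.full(9, math.nan))
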