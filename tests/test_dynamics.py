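import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitscape.dynamics import (ActuationInput, ScalingConstants, WalkerState,
                                expand_state, heelstrike_map, simulate_step,
                                step_map, swing_derivatives,
                                swing_foot_height)

from .oracles import heelstrike_matrix, integrate_swing_scipy

angles = st.floats(-0.6, 0.6)
rates = st.floats(-1.5, 1.5)


class TestSwingDerivatives:
    def test_upright_equilibrium(self):
        """With theta = phi = 0 and no swing rate, all accelerations vanish."""
        d = swing_derivatives(WalkerState(0.0, -0.3, 0.0, 0.0),
                              ActuationInput(0.1, 2.0, 2.0))
        assert d[1] == 0.0 and d[3] == 0.0

    def test_active_spring_selection(self):
        """phi > 0 engages k1, phi <= 0 engages k2; the difference between
        the two accelerations isolates the spring torque term."""
        u = ActuationInput(0.0, 3.0, 1.0)
        d_pos = swing_derivatives(WalkerState(0.2, -0.3, 0.1, -0.1), u)
        d_neg = swing_derivatives(WalkerState(0.2, -0.3, -0.1, -0.1), u)
        # same state magnitude, mirrored phi: isolate -k*phi contributions
        u_swap = ActuationInput(0.0, 1.0, 3.0)
        d_pos2 = swing_derivatives(WalkerState(0.2, -0.3, 0.1, -0.1), u_swap)
        assert d_pos[3] - d_pos2[3] == pytest.approx(-(3.0 - 1.0) * 0.1,
                                                     abs=1e-14)
        assert d_neg[3] == pytest.approx(
            swing_derivatives(WalkerState(0.2, -0.3, -0.1, -0.1),
                              ActuationInput(0.0, 99.0, 1.0))[3], abs=1e-14)

    def test_against_symbolic_evaluation(self):
        """Numeric swing acceleration matches a sympy evaluation of the
        equations of motion."""
        sympy = pytest.importorskip("sympy")
        th, thd, ph, phd, k = sympy.symbols("th thd ph phd k")
        thdd = sympy.sin(th)
        phdd = (thdd + thd ** 2 * sympy.sin(ph)
                - sympy.cos(th) * sympy.sin(ph) - k * ph)
        subs = {th: 0.2, thd: -0.3, ph: 0.25, phd: -0.1, k: 0.5}
        expected = float(phdd.subs(subs))
        d = swing_derivatives(WalkerState(0.2, -0.3, 0.25, -0.1),
                              ActuationInput(0.0, 0.5, 0.5))
        assert d[3] == pytest.approx(expected, abs=1e-15)
        assert d[1] == pytest.approx(float(thdd.subs(subs)), abs=1e-15)


class TestHeelstrike:
    def test_upright_contact_is_identity_on_stance_rate(self):
        post = heelstrike_map(WalkerState(0.0, -0.7, 0.0, 0.0), 0.0)
        assert post == WalkerState(0.0, -0.7, 0.0, 0.0)

    def test_against_matrix_oracle(self):
        pre = WalkerState(-0.3, -0.4, -0.6, 0.2)
        M, v = heelstrike_matrix(pre.theta)
        expected = M @ pre.as_array() + v * 0.05
        post = heelstrike_map(pre, 0.05)
        np.testing.assert_allclose(post.as_array(), expected, atol=1e-15)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(theta=angles, theta_dot=rates, P=st.floats(0.0, 1.0))
    def test_geometry_rows_are_impulse_free(self, theta, theta_dot, P):
        """theta+ = -theta- and phi+ = -2 theta- regardless of push-off."""
        post = heelstrike_map(WalkerState(theta, theta_dot, 2 * theta,
                                          0.1), P)
        assert post.theta == -theta
        assert post.phi == -2 * theta

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(theta=angles, theta_dot=rates, P=st.floats(0.0, 1.0))
    def test_collision_dissipates(self, theta, theta_dot, P):
        """Hip speed after the inelastic collision never exceeds the
        post-push-off speed sqrt(theta_dot^2 + P^2)."""
        post = heelstrike_map(WalkerState(theta, theta_dot, 2 * theta,
                                          0.0), P)
        assert post.theta_dot ** 2 <= theta_dot ** 2 + P ** 2 + 1e-12

    def test_rejects_negative_impulse(self):
        with pytest.raises(ValueError):
            heelstrike_map(WalkerState(-0.3, -0.4, -0.6, 0.2), -0.1)
        with pytest.raises(ValueError):
            ActuationInput(-0.01, 1.0, 1.0)


class TestSwingFootHeight:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(theta=angles)
    def test_zero_at_scuff_and_contact(self, theta):
        assert swing_foot_height(WalkerState(theta, 0, 0.0, 0)) == \
            pytest.approx(0.0, abs=1e-15)
        assert swing_foot_height(WalkerState(theta, 0, 2 * theta, 0)) == \
            pytest.approx(0.0, abs=1e-15)

    def test_mid_swing_height_matches_trig(self):
        # between the scuff and contact configurations the point foot dips
        # below ground level (a standard artifact of this model): the
        # direct trigonometric evaluation is negative here
        expected = np.cos(0.25) - np.cos(0.25 - 0.1)
        h = swing_foot_height(WalkerState(0.25, 0, 0.1, 0))
        assert h == pytest.approx(expected, abs=1e-15)
        assert expected < 0


class TestSimulateStep:
    def test_limit_cycle_closure(self, centre_gait):
        """One step from the fixed point returns to the fixed point."""
        res = simulate_step(expand_state(centre_gait.x_star),
                            centre_gait.u_nominal)
        assert res.completed
        nxt = res.start_state_next
        err = np.abs(nxt.reduced() - centre_gait.x_star).max()
        assert err <= 10 * 1e-11
        # step outputs define SL and SF consistently
        assert res.step_length == pytest.approx(
            2 * abs(np.sin(res.end_state_pre_collision.theta)))
        assert res.step_frequency * res.step_time == pytest.approx(1.0)

    def test_tilted_past_horizontal_falls(self):
        res = simulate_step(WalkerState(1.6, -0.1, 0.2, 0.0),
                            ActuationInput(0.0, 1.0, 1.0))
        assert res.outcome == "fell"

    def test_insufficient_energy_rocks_back(self):
        # barely moving at a steep stance angle: cannot pass mid-stance
        res = simulate_step(WalkerState(0.35, -0.05, 0.7, 0.0),
                            ActuationInput(0.0, 1.0, 1.0))
        assert res.outcome in ("fell", "no_contact")

    def test_event_consistency_at_contact(self, centre_gait):
        res = simulate_step(expand_state(centre_gait.x_star),
                            centre_gait.u_nominal)
        pre = res.end_state_pre_collision
        assert abs(pre.phi - 2 * pre.theta) <= 1e-10
        assert abs(swing_foot_height(pre)) <= 1e-10

    def test_matches_scipy_oracle(self, centre_gait):
        """Compiled integrator agrees with an independent scipy DOP853
        piecewise integration, including the contact time."""
        u = ActuationInput(centre_gait.u_nominal.P, 2.5, 3.1)
        res = simulate_step(expand_state(centre_gait.x_star), u)
        t_ref, y_ref = integrate_swing_scipy(
            expand_state(centre_gait.x_star).as_array(), 2.5, 3.1)
        assert res.step_time == pytest.approx(t_ref, abs=1e-8)
        np.testing.assert_allclose(res.end_state_pre_collision.as_array(),
                                   y_ref, atol=1e-8)

    def test_swing_reversibility(self, centre_gait):
        """Integrating backward from the pre-collision state (velocities
        negated, time reversed) recovers the step-start state."""
        res = simulate_step(expand_state(centre_gait.x_star),
                            centre_gait.u_nominal)
        pre = res.end_state_pre_collision.as_array()
        back0 = pre * np.array([1.0, -1.0, 1.0, -1.0])
        k = centre_gait.u_nominal.k1
        _, y_back = integrate_swing_scipy(back0, k, k,
                                          t_end=res.step_time)
        start = expand_state(centre_gait.x_star).as_array()
        expected = start * np.array([1.0, -1.0, 1.0, -1.0])
        np.testing.assert_allclose(y_back, expected, atol=1e-8)

    def test_stance_energy_integral_conserved(self, centre_gait):
        """The stance pendulum energy theta_dot^2/2 - cos(theta) is an
        invariant of the swing phase (swing mass does not load the stance
        leg)."""
        res = simulate_step(expand_state(centre_gait.x_star),
                            centre_gait.u_nominal, record_trajectory=True)
        tr = res.trajectory
        E = 0.5 * tr.theta_dot ** 2 + np.cos(tr.theta)
        assert np.ptp(E.to_numpy()) < 1e-11

    def test_impulsive_energy_bookkeeping(self, centre_gait):
        """Push-off adds kinetic energy P^2/2 along the leg; the collision
        projects the hip velocity onto the new stance direction, never
        gaining energy."""
        res = simulate_step(expand_state(centre_gait.x_star),
                            centre_gait.u_nominal)
        pre = res.end_state_pre_collision
        P = centre_gait.u_nominal.P
        ke_before = 0.5 * pre.theta_dot ** 2
        ke_pushed = ke_before + 0.5 * P ** 2
        ke_after = 0.5 * res.start_state_next.theta_dot ** 2
        assert ke_after <= ke_pushed + 1e-14
        loss = ke_pushed - ke_after
        # the projection formula fixes the loss exactly
        c2 = np.cos(2 * pre.theta)
        s2 = np.sin(2 * pre.theta)
        lost_component = -s2 * pre.theta_dot + c2 * P
        assert loss == pytest.approx(0.5 * lost_component ** 2, abs=1e-12)


class TestStepMap:
    def test_reduced_map_matches_full_simulation(self, centre_gait):
        x2, y, status = step_map(centre_gait.x_star, centre_gait.u_nominal)
        assert status == "completed"
        np.testing.assert_allclose(x2, centre_gait.x_star, atol=1e-9)
        assert y[0] == pytest.approx(0.6, abs=1e-9)
        assert y[1] == pytest.approx(0.6, abs=1e-9)

    def test_expand_state_transition_structure(self):
        s = expand_state([0.3, -0.45])
        assert s.phi == pytest.approx(0.6)
        assert s.phi_dot == pytest.approx((1 - np.cos(0.6)) * -0.45)


def test_scaling_constants():
    sc = ScalingConstants(l=1.0, g=9.81)
    assert sc.time_scale == pytest.approx(np.sqrt(1 / 9.81))
    assert sc.frequency_scale == pytest.approx(np.sqrt(9.81))
    assert sc.velocity_scale == pytest.approx(np.sqrt(9.81))
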