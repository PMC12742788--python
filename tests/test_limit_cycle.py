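import numpy as np
import pytest

from gaitscape.dynamics import ScalingConstants
from gaitscape.limit_cycle import (GaitCache, GaitGrid, GaitSpec,
                                   gait_residual, solve_column,
                                   solve_limit_cycle,
                                   stiffness_zero_crossing,
                                   to_physical_units)
from gaitscape.control import run_steps


class TestGaitResidual:
    def test_vanishes_at_converged_gait(self, centre_gait):
        z = np.array([centre_gait.x_star[0], centre_gait.x_star[1],
                      centre_gait.u_nominal.P, centre_gait.u_nominal.k1])
        r, outcome = gait_residual(z, GaitSpec(0.6, 0.6), mode="single")
        assert outcome == "completed"
        assert np.max(np.abs(r)) <= 1e-10

    def test_target_terms_are_affine(self, centre_gait):
        z = np.array([centre_gait.x_star[0], centre_gait.x_star[1],
                      centre_gait.u_nominal.P, centre_gait.u_nominal.k1])
        r1, _ = gait_residual(z, GaitSpec(0.3, 0.6), mode="single")
        r2, _ = gait_residual(z, GaitSpec(0.6, 0.6), mode="single")
        # doubling the SL target shifts only the SL entry, by -0.3
        assert r1[2] - r2[2] == pytest.approx(0.3, abs=1e-14)
        np.testing.assert_allclose(r1[[0, 1, 3]], r2[[0, 1, 3]], atol=1e-14)

    def test_perturbed_candidate_matches_two_point_difference(self,
                                                              centre_gait):
        z = np.array([centre_gait.x_star[0], centre_gait.x_star[1],
                      centre_gait.u_nominal.P, centre_gait.u_nominal.k1])
        zp = z.copy()
        zp[0] += 1e-3
        spec = GaitSpec(0.6, 0.6)
        r0, _ = gait_residual(z, spec, mode="single")
        rp, _ = gait_residual(zp, spec, mode="single")
        # brute-force: the periodicity entries of the difference equal
        # F(x + e) - F(x) - e computed from two independent evaluations
        from gaitscape.dynamics import step_map, ActuationInput
        u = centre_gait.u_nominal
        f0, _, _ = step_map(z[:2], u)
        fp, _, _ = step_map(zp[:2], u)
        expected = (fp - zp[:2]) - (f0 - z[:2])
        np.testing.assert_allclose(rp[:2] - r0[:2], expected, atol=1e-12)

    def test_failure_is_distinguished(self):
        # a candidate that cannot complete a step reports the outcome name
        r, outcome = gait_residual([0.3, -0.01, 0.0, 1.0],
                                   GaitSpec(0.6, 0.6), mode="single")
        assert r is None
        assert outcome in ("fell", "no_contact")


class TestSolveLimitCycle:
    def test_centre_gait_open_loop_periodicity(self, centre_gait):
        """Ten open-loop steps from the fixed point stay on it."""
        res = run_steps(centre_gait.x_star, 10,
                        u_const=centre_gait.u_nominal,
                        x_ref=centre_gait.x_star, conv_tol=1e-8)
        assert res.outcome == "converged"
        drift = np.abs(np.array([res.theta, res.theta_dot]).T
                       - centre_gait.x_star).max()
        assert drift <= 1e-8

    def test_single_and_double_spring_modes_agree(self, centre_gait):
        """The 5-unknown double-spring solve (with k1 = k2 symmetry
        equation) finds the same gait and equal stiffnesses."""
        gd = solve_limit_cycle(GaitSpec(0.6, 0.6), guess=centre_gait,
                               mode="double")
        assert gd.converged
        assert gd.u_nominal.k1 == pytest.approx(gd.u_nominal.k2, abs=1e-9)
        assert gd.u_nominal.k1 == pytest.approx(centre_gait.u_nominal.k1,
                                                abs=1e-8)
        np.testing.assert_allclose(gd.x_star, centre_gait.x_star,
                                   atol=1e-9)

    def test_resolving_from_own_solution_is_immediate(self, centre_gait):
        g = solve_limit_cycle(GaitSpec(0.6, 0.6), guess=centre_gait)
        assert g.converged
        assert g.n_iterations <= 1

    def test_achieved_targets(self, centre_gait):
        assert centre_gait.SL == pytest.approx(0.6, abs=1e-9)
        assert centre_gait.SF == pytest.approx(0.6, abs=1e-9)
        assert centre_gait.u_nominal.P > 0

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            GaitSpec(-0.1, 0.6)
        with pytest.raises(ValueError):
            GaitSpec(0.6, 2.0)


class TestContinuation:
    def test_fixture_grid_fully_converged(self, fixture_grid):
        n = fixture_grid.shape[0] * fixture_grid.shape[1]
        assert n == 49
        assert fixture_grid.n_converged == 49
        assert fixture_grid.residual_norm.max() <= 1e-10

    def test_fixture_gaits_reverify_periodicity(self, fixture_grid):
        for i in (0, 3, 6):
            for j in (0, 6):
                g = fixture_grid.gait(i, j)
                from gaitscape.dynamics import step_map
                x2, y, status = step_map(g.x_star, g.u_nominal)
                assert status == "completed"
                assert np.abs(x2 - g.x_star).max() <= 10 * 1e-11

    def test_nominal_pushoff_strictly_positive(self, fixture_grid,
                                               coarse_grid):
        assert (fixture_grid.P[fixture_grid.converged] > 0).all()
        assert (coarse_grid.P[coarse_grid.converged] > 0).all()

    def test_parameters_vary_smoothly(self, fixture_grid):
        audit = fixture_grid.smoothness_audit()
        # adjacent 0.01-increment cells: no family jumps
        jumps = dict(zip(audit["field"], audit["max_adjacent_jump"]))
        assert jumps["theta"] < 0.02
        assert jumps["theta_dot"] < 0.03
        assert jumps["P"] < 0.05
        assert jumps["k1"] < 0.3

    def test_coarse_grid_covers_gait_space(self, coarse_grid):
        assert coarse_grid.shape == (21, 21)
        assert coarse_grid.n_converged == 441

    def test_stiffness_sign_change_along_frequency_sweep(self, centre_gait):
        """At fixed SL the nominal hip stiffness changes sign near the
        swing leg's natural-frequency crossover."""
        sfs = np.round(np.arange(0.60, 0.19, -0.02), 10)
        col = solve_column(0.6, sfs, seed=centre_gait)
        assert all(g.converged for g in col)
        sf0 = stiffness_zero_crossing(col)
        assert 0.2 < sf0 < 0.32


class TestGaitCache:
    def test_lattice_solving_and_bounds(self, centre_gait):
        cache = GaitCache(centre_gait, increment=0.01)
        g = cache.gait_at(2, -1)
        assert g is not None and g.converged
        assert g.SL == pytest.approx(0.62, abs=1e-9)
        assert g.SF == pytest.approx(0.59, abs=1e-9)
        # outside the gait space: not a gait
        assert cache.spec_at(51, 0) is None


class TestGridIO:
    def test_round_trip_preserves_full_precision(self, fixture_grid,
                                                 tmp_path):
        p = tmp_path / "grid.csv"
        fixture_grid.to_csv(p)
        back = GaitGrid.from_csv(p)
        np.testing.assert_array_equal(back.sl_axis, fixture_grid.sl_axis)
        np.testing.assert_array_equal(back.theta, fixture_grid.theta)
        np.testing.assert_array_equal(back.k1, fixture_grid.k1)
        np.testing.assert_array_equal(back.converged,
                                      fixture_grid.converged)

    def test_gait_at_lookup(self, fixture_grid):
        g = fixture_grid.gait_at(0.6, 0.6)
        assert g.SL == pytest.approx(0.6)
        with pytest.raises(KeyError):
            fixture_grid.gait_at(0.605, 0.6)


class TestPhysicalUnits:
    def test_frequency_bounds_in_hertz(self, fixture_grid):
        df = to_physical_units(fixture_grid, ScalingConstants(l=1.0,
                                                              g=9.81))
        scale = np.sqrt(9.81)
        # 0.313 and 3.445 steps/s; the upper bound truncates to 3.44
        assert 0.1 * scale == pytest.approx(0.31, abs=5e-3)
        assert 1.1 * scale == pytest.approx(3.44, abs=1e-2)
        np.testing.assert_allclose(df["SF_Hz"], df["SF"] * scale)
        np.testing.assert_allclose(df["SL_m"], df["SL"])

    def test_unit_scales_identity(self, fixture_grid):
        df = to_physical_units(fixture_grid, ScalingConstants(l=1.0, g=1.0))
        np.testing.assert_array_equal(df["SF_Hz"], df["SF"])
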