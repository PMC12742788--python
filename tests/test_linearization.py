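import numpy as np
import pandas as pd
import pytest

from gaitscape.dynamics import step_map
from gaitscape.linearization import (LinearizedMaps,
                                     classify_stability,
                                     controllability_test,
                                     finite_difference_A,
                                     finite_difference_BCD, linearize_gait,
                                     locate_zero_boundary, stability_grid)


class TestStateJacobian:
    def test_forward_and_central_differences_agree(self, centre_gait):
        A_fwd = finite_difference_A(centre_gait, 1e-7)
        A_ctr = finite_difference_A(centre_gait, 1e-6, central=True)
        rel = np.max(np.abs(A_fwd - A_ctr)) / np.max(np.abs(A_ctr))
        assert rel <= 1e-4

    def test_probe_sizes_sit_in_linear_regime(self, centre_gait):
        """Estimates converge over probe sizes spanning 1e-8..1e-5: the
        stated probe is above integration noise and below curvature."""
        As = [finite_difference_A(centre_gait, d)
              for d in (1e-8, 1e-7, 1e-6, 1e-5)]
        for A1, A2 in zip(As, As[1:]):
            assert np.max(np.abs(A1 - A2)) <= 1e-3

    def test_one_step_prediction(self, centre_gait):
        """A small state deviation propagates through one nonlinear step
        as A @ dx to high accuracy."""
        A = finite_difference_A(centre_gait, 1e-7)
        rng = np.random.default_rng(7)
        for _ in range(3):
            dx = rng.standard_normal(2)
            dx *= 1e-6 / np.linalg.norm(dx)
            x2, _, status = step_map(centre_gait.x_star + dx,
                                     centre_gait.u_nominal)
            assert status == "completed"
            pred = centre_gait.x_star + A @ dx
            assert np.linalg.norm(x2 - pred) <= 1e-9

    def test_centre_gait_is_open_loop_stable(self, centre_maps):
        assert centre_maps.max_eig_magnitude < 1.0


class TestInputOutputMatrices:
    def test_pushoff_structural_zeros(self, fixture_grid):
        """Push-off acts at the end of the step: it cannot move the next
        stance angle (B row theta) nor the executed step's SL/SF (D)."""
        for i, j in ((0, 0), (3, 3), (6, 6), (0, 6)):
            g = fixture_grid.gait(i, j)
            B, C, D = finite_difference_BCD(g, mode="double")
            assert abs(B[0, 0]) <= 1e-10
            assert abs(D[0, 0]) <= 1e-10
            assert abs(D[1, 0]) <= 1e-10

    def test_split_stiffness_columns_sum_to_single(self, centre_gait):
        """To first order, perturbing k1 and k2 separately adds up to
        perturbing the single shared stiffness."""
        Bd, _, Dd = finite_difference_BCD(centre_gait, mode="double")
        Bs, _, Ds = finite_difference_BCD(centre_gait, mode="single")
        np.testing.assert_allclose(Bd[:, 1] + Bd[:, 2], Bs[:, 1],
                                   atol=2e-5)
        np.testing.assert_allclose(Dd[:, 1] + Dd[:, 2], Ds[:, 1],
                                   atol=2e-5)

    def test_mode_shapes(self, centre_gait):
        ms = linearize_gait(centre_gait, mode="single")
        md = linearize_gait(centre_gait, mode="double")
        assert ms.B.shape == (2, 2) and ms.D.shape == (2, 2)
        assert md.B.shape == (2, 3) and md.D.shape == (2, 3)
        np.testing.assert_allclose(ms.A, md.A, atol=1e-12)


class TestStabilityClassification:
    def test_region_labels_on_synthetic_map(self):
        """Left-unstable / center-stable / right-unstable banding is
        recovered from a constructed eigenvalue table."""
        sls = [0.4, 0.5]
        sfs = [0.1, 0.2, 0.3, 0.4, 0.5]
        rows = []
        for sl in sls:
            for k, sf in enumerate(sfs):
                eig = [5.0, 0.8, 0.7, 0.9, 1.4][k]
                rows.append({"SL": sl, "SF": sf, "max_eig": eig})
        rep = classify_stability(pd.DataFrame(rows))
        df = rep.to_dataframe().set_index(["SL", "SF"])
        assert df.loc[(0.4, 0.1), "region"] == "left"
        assert df.loc[(0.4, 0.3), "region"] == "center"
        assert df.loc[(0.5, 0.5), "region"] == "right"
        assert bool(df.loc[(0.4, 0.2), "stable"]) is True

    def test_gait_space_region_structure(self, coarse_grid):
        """Unstable at very low SF and at high-SF/long-SL combinations,
        stable in between."""
        eig = stability_grid(coarse_grid)
        rep = classify_stability(eig)
        df = rep.to_dataframe()
        assert (df["region"] == "center").any()
        assert (df["region"] == "left").any()
        assert (df["region"] == "right").any()
        # left region sits at lower SF than the stable band
        left_sf = df.loc[df.region == "left", "SF"].mean()
        center_sf = df.loc[df.region == "center", "SF"].mean()
        assert left_sf < center_sf


class TestControllability:
    def test_synthetic_full_rank(self):
        maps = LinearizedMaps(A=np.zeros((2, 2)),
                              B=np.hstack([np.eye(2), np.zeros((2, 1))]),
                              C=np.eye(2), D=np.zeros((2, 3)),
                              mode="double", fd_step=1e-7)
        rep = controllability_test(maps)
        assert rep.rank == 2 and rep.controllable

    def test_double_spring_full_rank_across_fixture(self, fixture_grid):
        for i in (0, 3, 6):
            for j in (0, 3, 6):
                maps = linearize_gait(fixture_grid.gait(i, j),
                                      mode="double")
                rep = controllability_test(maps)
                assert rep.controllable
                sv = rep.singular_values
                assert sv[-1] / sv[0] > 1e-2

    def test_zero_boundary_loses_rank(self, coarse_grid):
        """On the single-spring zero-boundary the stiffness and coupling
        sensitivities vanish together: the controllability matrix becomes
        numerically rank deficient, while the double-spring walker keeps
        full rank at the same gait."""
        seed = coarse_grid.gait_at(0.9, 0.45)
        g, m = locate_zero_boundary(0.9, (0.40, 0.55), seed)
        rep = controllability_test(m)
        sv = rep.singular_values
        ratio_on = sv[-1] / sv[0]
        assert ratio_on < 1e-3
        # bisected entry, at the finite-difference noise floor (~1e-5)
        assert abs(m.B[0, 1]) < 1e-4
        assert abs(m.A[0, 1]) < 1e-2      # co-vanishing couplings
        assert abs(m.B[1, 1]) < 1e-3
        # off the boundary the same row is healthily controllable
        off = linearize_gait(coarse_grid.gait_at(0.9, 0.6), mode="single")
        sv_off = controllability_test(off).singular_values
        assert sv_off[-1] / sv_off[0] > 1e-2
        # the second spring restores control authority
        md = linearize_gait(g, mode="double")
        repd = controllability_test(md)
        assert repd.controllable
        assert repd.singular_values[-1] / repd.singular_values[0] > 0.1
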