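"""Linear unmixing, exclusion polygons, STED trajectory and Tau-STED filter."""

import numpy as np
import pytest

import phasorsted as ps
from phasorsted.phasor import PhasorField, analytic_phasor
from phasorsted.separation import (Component, ExclusionPolygon,
                                   reflection_exclusion_triangle,
                                   sted_trajectory, tau_sted_filter, unmix,
                                   apply_exclusion)

from conftest import OMEGA

A = Component("A", 0.30, 0.45)
B = Component("B", 0.60, 0.45)
C = Component("C", 0.45, 0.20)


def _field(g, s, intensity):
    g = np.atleast_2d(np.asarray(g, dtype=float))
    s = np.atleast_2d(np.asarray(s, dtype=float))
    i = np.atleast_2d(np.asarray(intensity, dtype=float))
    return PhasorField(g=g, s=s, intensity=i, omega=OMEGA)


class TestTwoComponentUnmix:
    def test_pixel_at_vertex_gets_one_hot_fraction(self):
        f = _field([A.g, B.g], [A.s, B.s], [100.0, 40.0])
        res = unmix(f, [A, B])
        np.testing.assert_allclose(res.fractions[:, 0, 0], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(res.fractions[:, 0, 1], [0.0, 1.0], atol=1e-12)

    def test_midpoint_pixel_splits_photons_evenly(self):
        f = _field([(A.g + B.g) / 2], [(A.s + B.s) / 2], [200.0])
        res = unmix(f, [A, B])
        np.testing.assert_allclose(res.component_images[:, 0, 0],
                                   [100.0, 100.0], atol=1e-9)

    def test_out_of_segment_pixels_clamp_and_are_counted(self):
        f = _field([0.9], [0.45], [50.0])  # beyond B along AB
        res = unmix(f, [A, B])
        np.testing.assert_allclose(res.fractions[:, 0, 0], [0.0, 1.0], atol=1e-12)
        assert res.n_clamped == 1

    def test_residual_is_distance_to_segment(self):
        f = _field([0.45], [0.55], [10.0])
        res = unmix(f, [A, B])
        assert res.residual[0, 0] == pytest.approx(0.10, abs=1e-12)

    def test_component_images_conserve_intensity_exactly(self):
        rng = np.random.default_rng(1)
        f = _field(rng.uniform(0, 1, (16, 16)), rng.uniform(0, 0.6, (16, 16)),
                   rng.integers(1, 500, (16, 16)).astype(float))
        res = unmix(f, [A, B])
        np.testing.assert_array_equal(res.component_images.sum(axis=0),
                                      f.intensity)

    def test_coincident_components_are_rejected(self):
        f = _field([0.5], [0.4], [10.0])
        with pytest.raises(ValueError, match="non-coincident"):
            unmix(f, [A, Component("A2", A.g, A.s)])


class TestThreeComponentUnmix:
    def test_interior_pixel_weights_reconstruct_position(self):
        w = np.array([0.2, 0.5, 0.3])
        g = w @ [A.g, B.g, C.g]
        s = w @ [A.s, B.s, C.s]
        res = unmix(_field([g], [s], [100.0]), [A, B, C])
        np.testing.assert_allclose(res.fractions[:, 0, 0], w, atol=1e-10)
        assert res.residual[0, 0] < 1e-10

    def test_barycentric_matches_constrained_least_squares_oracle(self):
        """For interior pixels the barycentric weights equal the solution
        of min ||z - Cw|| subject to w >= 0, sum w = 1 (solved here by an
        independent SLSQP quadratic program)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(7)
        pts = np.array([[A.g, A.s], [B.g, B.s], [C.g, C.s]])
        w_true = rng.dirichlet([1, 1, 1], size=100)
        z = w_true @ pts
        res = unmix(_field(z[:, 0][None, :], z[:, 1][None, :],
                           np.full((1, 100), 10.0)), [A, B, C])
        for i in range(100):
            obj = lambda w: np.sum((pts.T @ w - z[i]) ** 2)
            sol = minimize(obj, x0=np.full(3, 1 / 3), method="SLSQP",
                           bounds=[(0, 1)] * 3,
                           constraints={"type": "eq",
                                        "fun": lambda w: w.sum() - 1.0},
                           tol=1e-14)
            np.testing.assert_allclose(res.fractions[:, 0, i], sol.x, atol=1e-6)

    def test_exterior_pixels_clamp_negatives_and_renormalize(self):
        res = unmix(_field([0.9], [0.05], [90.0]), [A, B, C])
        fr = res.fractions[:, 0, 0]
        assert (fr >= 0).all()
        assert fr.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.n_clamped == 1

    def test_collinear_components_warn_and_flag_low_confidence(self):
        coll = [Component("a", 0.2, 0.3), Component("b", 0.4, 0.3),
                Component("c", 0.6, 0.3)]
        with pytest.warns(UserWarning, match="collinear"):
            res = unmix(_field([0.4], [0.31], [10.0]), coll)
        assert res.low_confidence

    def test_all_invalid_pixels_is_an_error(self):
        f = _field([np.nan], [np.nan], [0.0])
        with pytest.raises(ValueError, match="invalid"):
            unmix(f, [A, B])


class TestExclusionPolygons:
    def test_polygon_covering_plane_zeroes_everything(self):
        f = _field([0.2, 0.8], [0.1, 0.5], [10.0, 20.0])
        poly = ExclusionPolygon([[-1, -1], [2, -1], [2, 1], [-1, 1]])
        out = apply_exclusion(f, [poly])
        assert (out.intensity == 0).all()

    def test_empty_polygon_list_is_identity(self):
        f = _field([0.2, 0.8], [0.1, 0.5], [10.0, 20.0])
        out = apply_exclusion(f, [])
        np.testing.assert_array_equal(out.intensity, f.intensity)
        np.testing.assert_array_equal(out.g, f.g)

    def test_boundary_points_count_as_inside(self):
        f = _field([0.5], [0.0], [5.0])  # exactly on the polygon edge
        poly = ExclusionPolygon([[0.0, 0.0], [1.0, 0.0], [0.5, 0.4]])
        out = apply_exclusion(f, [poly])
        assert out.intensity[0, 0] == 0

    def test_reflection_triangle_removes_zero_lifetime_keeps_dye(self):
        g1, s1 = analytic_phasor(1.7, OMEGA)
        f = _field([1.0, g1], [0.0, s1], [100.0, 100.0])
        out = apply_exclusion(f, [reflection_exclusion_triangle()])
        assert out.intensity[0, 0] == 0
        assert out.intensity[0, 1] == 100.0

    def test_degenerate_polygons_are_rejected(self):
        with pytest.raises(ValueError, match="vertices"):
            ExclusionPolygon([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="simple"):
            ExclusionPolygon([[0, 0], [1, 1], [1, 0], [0, 1]])


class TestStedTrajectory:
    def test_zero_depletion_is_a_single_natural_point(self):
        comp = ps.component_from_lifetime("d", 3.2, OMEGA)
        traj = sted_trajectory(comp, 0.0, 1, OMEGA)
        np.testing.assert_allclose(traj, [[comp.g, comp.s]], atol=1e-12)

    def test_infinite_depletion_limit_is_zero_lifetime_point(self):
        comp = ps.component_from_lifetime("d", 3.2, OMEGA)
        traj = sted_trajectory(comp, 1e6, 3, OMEGA)
        np.testing.assert_allclose(traj[-1], [1.0, 0.0], atol=1e-4)

    def test_trajectory_lifetimes_follow_rate_addition(self):
        """k in [0, 2] ns^-1 in 5 steps on tau = 3.2 ns: observed lifetimes
        1/(1/tau + k) = {3.2, 1.2308, 0.7619, 0.5517, 0.4324} ns, each on
        the universal circle."""
        comp = ps.component_from_lifetime("d", 3.2, OMEGA)
        traj = sted_trajectory(comp, 2.0, 5, OMEGA)
        k = np.linspace(0, 2, 5)
        taus = 1.0 / (1.0 / 3.2 + k)
        np.testing.assert_allclose(taus, [3.2, 1.23077, 0.76190, 0.55172,
                                          0.43243], atol=1e-5)
        g, s = analytic_phasor(taus, OMEGA)
        np.testing.assert_allclose(traj, np.stack([g, s], axis=1), atol=1e-12)
        # ordered from the natural position toward (1, 0)
        assert np.all(np.diff(traj[:, 0]) > 0)
        np.testing.assert_allclose((traj[:, 0] - 0.5) ** 2 + traj[:, 1] ** 2,
                                   0.25, atol=1e-12)

    def test_missing_nominal_tau_is_rejected(self):
        with pytest.raises(ValueError, match="nominal_tau"):
            sted_trajectory(Component("x", 0.4, 0.4), 1.0, 5, OMEGA)


class TestTauStedFilter:
    def _traj(self):
        return sted_trajectory(ps.component_from_lifetime("d", 3.2, OMEGA),
                               10.0, 30, OMEGA)

    def test_neutral_settings_are_identity(self):
        rng = np.random.default_rng(0)
        f = _field(rng.uniform(0.2, 0.9, (8, 8)), rng.uniform(0.1, 0.5, (8, 8)),
                   rng.uniform(1, 100, (8, 8)))
        out = tau_sted_filter(f, self._traj(), center_weight=0.0,
                              kernel_scale=None)
        np.testing.assert_allclose(out, f.intensity, atol=1e-12)

    def test_natural_position_keeps_full_weight_depleted_loses(self):
        g0, s0 = analytic_phasor(3.2, OMEGA)
        g1, s1 = analytic_phasor(0.5, OMEGA)
        f = _field([g0, g1], [s0, s1], [100.0, 100.0])
        out = tau_sted_filter(f, self._traj(), center_weight=1.0,
                              kernel_scale=None)
        assert out[0, 0] == pytest.approx(100.0, abs=1e-6)
        assert out[0, 1] < 30.0

    def test_reflection_pixels_are_suppressed(self):
        f = _field([1.0], [0.0], [500.0])
        out = tau_sted_filter(f, self._traj(),
                              exclusions=[reflection_exclusion_triangle()],
                              center_weight=1.0, kernel_scale=0.05)
        assert out[0, 0] == 0.0

    def test_off_trajectory_contributions_are_downweighted(self):
        g0, s0 = analytic_phasor(3.2, OMEGA)
        f = _field([g0, g0], [s0, s0 - 0.2], [100.0, 100.0])
        out = tau_sted_filter(f, self._traj(), center_weight=0.0,
                              kernel_scale=0.05)
        assert out[0, 0] == pytest.approx(100.0, abs=1e-6)
        assert out[0, 1] < 1.0

    def test_degenerate_trajectory_is_rejected(self):
        f = _field([0.5], [0.4], [10.0])
        with pytest.raises(ValueError, match="trajectory"):
            tau_sted_filter(f, np.array([[0.4, 0.4]]))

    def test_filtering_improves_sted_frc_resolution(self, five_color_sted_ch1_256,
                                                    calibration):
        """Down-weighting short-lifetime periphery photons sharpens the
        image: FRC resolution of the Tau-STED-filtered image beats the
        unfiltered STED image.  Each photon half is filtered independently
        so the comparison stays unbiased."""
        from phasorsted.phasor import apply_calibration, phasor_transform, spatial_filter

        traj = self._traj()
        a, b = ps.split_photons(five_color_sted_ch1_256, seed=11)

        def filtered(img):
            f = spatial_filter(apply_calibration(phasor_transform(img),
                                                 calibration), "median", 2)
            return tau_sted_filter(f, traj, center_weight=1.0, kernel_scale=0.08)

        r_raw = ps.frc_curve(a.intensity, b.intensity, 25.0)
        r_fil = ps.frc_curve(filtered(a), filtered(b), 25.0)
        assert r_fil.resolution < r_raw.resolution
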