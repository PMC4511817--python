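"""Slope and curvature operators: exactness on polynomials and oracle checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reefmetrics import ElevationGrid, curvature_raster, fit_quadratic_window, slope_raster

from conftest import grid_from_function

coeff = st.floats(-2.0, 2.0, allow_nan=False)


def quadratic_grid(a, b, c, d, e, f, cell_size=1.0, n=9):
    """DEM sampling z = a x^2 + b y^2 + c xy + d x + e y + f."""
    return grid_from_function(
        lambda x, y: a * x**2 + b * y**2 + c * x * y + d * x + e * y + f,
        extent=(n * cell_size, n * cell_size),
        cell_size=cell_size,
    )


class TestQuadFit:
    def test_flat_window_gives_zero_coefficients(self):
        g = ElevationGrid(np.full((3, 3), 5.0), cell_size=1.0)
        q = fit_quadratic_window(g, 1, 1)
        assert (q.D, q.E, q.F, q.G, q.H) == (0, 0, 0, 0, 0)

    def test_plane_gradient_recovered_exactly(self):
        g = grid_from_function(lambda x, y: 0.3 * x, extent=(3, 3), cell_size=1.0)
        q = fit_quadratic_window(g, 1, 1)
        assert q.G == pytest.approx(0.3, abs=1e-15)
        assert (q.D, q.E, q.F, q.H) == pytest.approx((0, 0, 0, 0), abs=1e-15)

    def test_centered_paraboloid_coefficients(self):
        # z = -0.01 (x^2 + y^2) centred on the window: hand evaluation of the
        # nine samples gives D = E = -0.01, F = G = H = 0
        vals = np.empty((3, 3))
        for r in range(3):
            for c in range(3):
                x, y = c - 1, 1 - r
                vals[r, c] = -0.01 * (x**2 + y**2)
        g = ElevationGrid(vals, cell_size=1.0)
        q = fit_quadratic_window(g, 1, 1)
        assert q.D == pytest.approx(-0.01, abs=1e-15)
        assert q.E == pytest.approx(-0.01, abs=1e-15)
        assert (q.F, q.G, q.H) == pytest.approx((0, 0, 0), abs=1e-15)

    def test_masked_neighbour_is_incomplete_window(self):
        vals = np.zeros((3, 3))
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = True
        g = ElevationGrid(vals, cell_size=1.0, nodata_mask=mask)
        with pytest.raises(ValueError, match="incomplete window"):
            fit_quadratic_window(g, 1, 1)

    @given(a=coeff, b=coeff, c=coeff, d=coeff, e=coeff)
    def test_matches_least_squares_fit_oracle(self, a, b, c, d, e):
        """The 3x3 stencil must agree with a brute-force LSQ quadratic fit."""
        g = quadratic_grid(a, b, c, d, e, 0.7, cell_size=0.5, n=5)
        row, col = 2, 2
        q = fit_quadratic_window(g, row, col)
        # assemble the 9 points in window-local world coordinates
        pts, zs = [], []
        L = g.cell_size
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                pts.append((dc * L, -dr * L))
                zs.append(g.values[row + dr, col + dc])
        A = np.array([[x * x, y * y, x * y, x, y, 1.0] for x, y in pts])
        coefs, *_ = np.linalg.lstsq(A, np.array(zs), rcond=None)
        # LSQ on an exact quadratic recovers it: D = z_xx/2, E = z_yy/2, F = z_xy
        np.testing.assert_allclose(
            [q.D, q.E, q.F, q.G, q.H],
            [coefs[0], coefs[1], coefs[2], coefs[3], coefs[4]],
            rtol=1e-10, atol=1e-10,
        )


class TestSlope:
    def test_flat_grid_zero_slope_both_units(self, flat_grid):
        for units in ("percent", "degrees"):
            s = slope_raster(flat_grid, units=units)
            np.testing.assert_allclose(s.values[1:-1, 1:-1], 0.0)
            assert s.nodata_mask[0].all() and s.nodata_mask[-1].all()

    def test_unit_plane_is_100_percent_and_45_degrees(self, ramp_grid):
        sp = slope_raster(ramp_grid, units="percent")
        sd = slope_raster(ramp_grid, units="degrees")
        np.testing.assert_allclose(sp.values[1:-1, 1:-1], 100.0, rtol=1e-12)
        np.testing.assert_allclose(sd.values[1:-1, 1:-1], 45.0, rtol=1e-12)

    def test_hand_applied_weighted_difference(self):
        # rows all (1, 2, 3), L = 1: dz/dx = 1, dz/dy = 0 -> 100 %
        g = ElevationGrid(np.tile([1.0, 2.0, 3.0], (3, 1)), cell_size=1.0)
        s = slope_raster(g, units="percent")
        assert s.values[1, 1] == pytest.approx(100.0)

    @given(d=coeff, e=coeff)
    def test_exact_on_arbitrary_planes(self, d, e):
        g = grid_from_function(lambda x, y: d * x + e * y, extent=(5, 5), cell_size=1.0)
        s = slope_raster(g, units="percent")
        expected = 100.0 * np.hypot(d, e)
        np.testing.assert_allclose(s.values[1:-1, 1:-1], expected, rtol=1e-10, atol=1e-10)

    def test_small_grid_rejected(self):
        g = ElevationGrid(np.zeros((2, 2)), cell_size=1.0)
        with pytest.raises(ValueError, match="3x3"):
            slope_raster(g)

    def test_scaling_doubles_tangent(self, rng=np.random.default_rng(3)):
        vals = rng.normal(size=(8, 8))
        g1 = ElevationGrid(vals, cell_size=1.0)
        g2 = ElevationGrid(2 * vals, cell_size=1.0)
        s1 = slope_raster(g1).values
        s2 = slope_raster(g2).values
        np.testing.assert_allclose(s2[1:-1, 1:-1], 2 * s1[1:-1, 1:-1], rtol=1e-12)

    def test_rotation_consistency(self, rng=np.random.default_rng(4)):
        vals = rng.normal(size=(7, 7))
        s = slope_raster(ElevationGrid(vals, cell_size=1.0)).values
        s_rot = slope_raster(ElevationGrid(np.rot90(vals), cell_size=1.0)).values
        np.testing.assert_allclose(s_rot, np.rot90(s), rtol=1e-12)


class TestCurvature:
    def test_planes_have_zero_curvature(self, ramp_grid):
        # second differences of an exact plane cancel only to round-off, which
        # the x100 scaling and 1/L^2 inflate; 1e-9 is the claimed exactness
        for r in curvature_raster(ramp_grid):
            np.testing.assert_allclose(r.values[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_dome_combined_positive_four(self):
        g = grid_from_function(
            lambda x, y: -0.01 * ((x - 5) ** 2 + (y - 5) ** 2), extent=(10, 10), cell_size=1.0
        )
        combined, _, _ = curvature_raster(g)
        np.testing.assert_allclose(combined.values[1:-1, 1:-1], 4.0, rtol=1e-9)

    def test_bowl_is_antisymmetric_to_dome(self):
        dome = grid_from_function(
            lambda x, y: -0.01 * ((x - 5) ** 2 + (y - 5) ** 2), extent=(10, 10), cell_size=1.0
        )
        bowl = grid_from_function(
            lambda x, y: 0.01 * ((x - 5) ** 2 + (y - 5) ** 2), extent=(10, 10), cell_size=1.0
        )
        for rd, rb in zip(curvature_raster(dome), curvature_raster(bowl)):
            np.testing.assert_allclose(
                rd.values[1:-1, 1:-1], -rb.values[1:-1, 1:-1], rtol=1e-9, atol=1e-12
            )

    @given(a=coeff, b=coeff, c=coeff, d=coeff, e=coeff)
    def test_exact_on_quadratics_against_closed_form(self, a, b, c, d, e):
        """Curvature from sampled quadratics must match analytic derivatives."""
        g = quadratic_grid(a, b, c, d, e, 0.0, cell_size=0.5, n=7)
        combined, profile, planform = curvature_raster(g)
        xs = g.x_centers()
        ys = g.y_centers()
        xx, yy = np.meshgrid(xs[1:-1], ys[1:-1])
        D, E, F = a, b, c
        G = 2 * a * xx + c * yy + d
        H = 2 * b * yy + c * xx + e
        denom = G**2 + H**2
        safe = np.where(denom > 0, denom, 1.0)
        exp_combined = -2 * (D + E) * 100.0
        exp_profile = np.where(denom > 0, 2 * (D * G**2 + E * H**2 + F * G * H) / safe, 0) * 100
        exp_planform = np.where(denom > 0, -2 * (D * H**2 + E * G**2 - F * G * H) / safe, 0) * 100
        np.testing.assert_allclose(
            combined.values[1:-1, 1:-1], exp_combined, rtol=1e-9, atol=1e-9
        )
        np.testing.assert_allclose(profile.values[1:-1, 1:-1], exp_profile, rtol=1e-9, atol=1e-9)
        np.testing.assert_allclose(
            planform.values[1:-1, 1:-1], exp_planform, rtol=1e-9, atol=1e-9
        )

    def test_cell_size_invariance_for_quadratics(self):
        for cs in (1.0, 0.5):
            g = grid_from_function(
                lambda x, y: -0.01 * ((x - 4) ** 2 + (y - 4) ** 2), extent=(8, 8), cell_size=cs
            )
            combined, _, _ = curvature_raster(g)
            np.testing.assert_allclose(combined.values[1:-1, 1:-1], 4.0, rtol=1e-9)

    def test_z_unit_scale_multiplies_and_validates(self):
        g = grid_from_function(
            lambda x, y: -0.01 * ((x - 5) ** 2 + (y - 5) ** 2), extent=(10, 10), cell_size=1.0
        )
        combined, _, _ = curvature_raster(g, z_unit_scale=2.0)
        np.testing.assert_allclose(combined.values[1:-1, 1:-1], 8.0, rtol=1e-9)
        with pytest.raises(ValueError, match="z_unit_scale"):
            curvature_raster(g, z_unit_scale=0.0)

    def test_nodata_neighbours_masked_in_rasters(self):
        vals = np.zeros((6, 6))
        mask = np.zeros((6, 6), dtype=bool)
        mask[3, 3] = True
        g = ElevationGrid(vals, cell_size=1.0, nodata_mask=mask)
        s = slope_raster(g)
        assert s.nodata_mask[2:5, 2:5].all()
        assert not s.nodata_mask[1, 1]
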