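import numpy as np
import pytest

from vortexlav import (ChamberMask, VelocitySeries, advect, compute_lavd,
                       mean_vorticity, sample_velocity, vorticity)
from vortexlav.scenes import VortexSpec, vortex_velocity

from conftest import rigid_rotation_series


class TestVorticity:
    def test_uniform_translation_zero(self):
        c = np.full((9, 9), 3.0)
        np.testing.assert_allclose(vorticity(c, c, 1.0).omega, 0.0)

    def test_solid_body_rotation_constant(self):
        # u = -y, v = x (array frame): omega = dv/dx - du/dy = 2 exactly (linear field)
        rows, cols = np.indices((11, 11), dtype=float)
        om = vorticity(-rows, cols, 1.0).omega
        np.testing.assert_allclose(om, 2.0, atol=1e-12)

    def test_lamb_oseen_matches_closed_form(self):
        s, a, gamma = 1.0, 10.0, 200.0
        rows, cols = np.indices((81, 81), dtype=float)
        vor = VortexSpec(center=(40.0, 40.0), circulation=gamma,
                         core_radius=a, model="lamb_oseen")
        u, v = vortex_velocity(cols * s, rows * s, vor)
        om = vorticity(u, v, s).omega
        r = np.hypot(cols - 40, rows - 40)
        closed = -gamma / (np.pi * a**2) * np.exp(-(r**2) / a**2)  # array-frame sign
        peak = gamma / (np.pi * a**2)
        sel = (r >= 3) & (r <= 2 * a)
        assert np.abs(om[sel] - closed[sel]).max() / peak < 0.01

    def test_too_small_grid(self):
        with pytest.raises(ValueError):
            vorticity(np.zeros((2, 5)), np.zeros((2, 5)), 1.0)


class TestMeanVorticity:
    def test_constant_field(self):
        from vortexlav.lavd import VorticityField
        mask = ChamberMask(np.ones((6, 6), dtype=bool))
        assert mean_vorticity(VorticityField(np.full((6, 6), 2.0)), mask) == pytest.approx(2.0)

    def test_checkerboard_cancels(self):
        from vortexlav.lavd import VorticityField
        rows, cols = np.indices((6, 6))
        omega = np.where((rows + cols) % 2 == 0, 1.0, -1.0)
        assert mean_vorticity(VorticityField(omega), ChamberMask(np.ones((6, 6), bool))) == 0.0

    def test_matches_brute_force(self):
        from vortexlav.lavd import VorticityField
        rng = np.random.default_rng(5)
        omega = rng.normal(size=(10, 10))
        mask = ChamberMask(rng.random((10, 10)) > 0.4)
        expected = omega[mask.pixels].sum() / mask.n_pixels
        assert mean_vorticity(VorticityField(omega), mask) == pytest.approx(expected)

    def test_empty_mask(self):
        from vortexlav.lavd import VorticityField
        with pytest.raises(ValueError):
            mean_vorticity(VorticityField(np.zeros((4, 4))), ChamberMask(np.zeros((4, 4), bool)))


class TestSampleVelocity:
    def test_exact_at_nodes(self, rankine_scene):
        series, _, _, _ = rankine_scene
        s = series.geometry.pixel_spacing
        pos = np.array([[10 * s, 20 * s]])
        out = sample_velocity(series, pos, series.times[1])
        assert out[0, 0] == pytest.approx(series.u[1, 20, 10])
        assert out[0, 1] == pytest.approx(series.v[1, 20, 10])

    def test_bilinear_exact_on_linear_field(self):
        series, (cx, cy) = rigid_rotation_series(1.0)
        pos = np.array([[cx + 0.123, cy - 0.321]])
        out = sample_velocity(series, pos, 0.1)
        # u = omega*(y-cy), v = -omega*(x-cx): bilinear is exact on linear fields
        assert out[0, 0] == pytest.approx(-0.321, abs=1e-12)
        assert out[0, 1] == pytest.approx(-0.123, abs=1e-12)

    def test_time_out_of_range(self, rankine_scene):
        series, _, _, _ = rankine_scene
        with pytest.raises(ValueError):
            sample_velocity(series, np.array([[0.5, 0.5]]), series.times[-1] + 1.0)


class TestAdvect:
    def test_zero_velocity_identity_flow_map(self, rankine_scene):
        series, _, _, _ = rankine_scene
        zero = VelocitySeries(u=np.zeros_like(series.u), v=np.zeros_like(series.v),
                              times=series.times, geometry=series.geometry)
        seeds = np.array([[1.0, 1.0], [2.0, 3.0]])
        traj = advect(zero, seeds, 0.0, 1.0, 0.05)
        np.testing.assert_allclose(traj.final, seeds, atol=1e-14)

    def test_uniform_flow_exact(self):
        from vortexlav import ScanGeometry
        g = ScanGeometry(1.0, 6.0, 0.5, 100.0, 3)
        shape = (3, 21, 21)
        series = VelocitySeries(u=np.full(shape, 2.0), v=np.zeros(shape),
                                times=np.array([0.0, 0.5, 1.0]), geometry=g)
        traj = advect(series, np.array([[1.0, 10.0]]), 0.0, 1.0, 0.1)
        np.testing.assert_allclose(traj.final[0], [3.0, 10.0], atol=1e-12)

    def test_circular_orbit_quarter_turn(self):
        # conventional CCW rotation Omega = pi/2 for 1 s turns (r, 0) into (0, r);
        # in array coordinates that endpoint is (cx, cy - r)
        series, (cx, cy) = rigid_rotation_series(np.pi / 2)
        r = 1.0
        traj = advect(series, np.array([[cx + r, cy]]), 0.0, 1.0, 0.005)
        np.testing.assert_allclose(traj.final[0], [cx, cy - r], atol=1e-4 * r)
        radius = np.hypot(*(traj.positions[:, 0, :] - [cx, cy]).T)
        assert np.abs(radius - r).max() < 1e-4 * r

    def test_radius_conservation_full_revolution(self):
        series, (cx, cy) = rigid_rotation_series(2 * np.pi, n_frames=3, frame_interval=0.5)
        r = 1.5
        traj = advect(series, np.array([[cx + r, cy]]), 0.0, 1.0, 0.002)
        radius = np.hypot(*(traj.positions[:, 0, :] - [cx, cy]).T)
        assert np.abs(radius - r).max() < 1e-3 * r

    def test_leaving_domain_freezes(self):
        from vortexlav import ScanGeometry
        g = ScanGeometry(1.0, 6.0, 0.5, 100.0, 3)
        shape = (3, 11, 11)
        series = VelocitySeries(u=np.full(shape, 50.0), v=np.zeros(shape),
                                times=np.array([0.0, 0.5, 1.0]), geometry=g)
        traj = advect(series, np.array([[5.0, 5.0]]), 0.0, 1.0, 0.05)
        assert not traj.alive[-1, 0]
        assert traj.final[0, 0] <= 10.0

    def test_dt_validation(self, rankine_scene):
        series, _, _, _ = rankine_scene
        with pytest.raises(ValueError):
            advect(series, np.array([[1.0, 1.0]]), 0.0, 0.1, 0.5)


class TestComputeLavd:
    def test_rigid_rotation_null(self):
        # omega == mean omega == 2*Omega everywhere: the deviation vanishes
        series, (cx, cy) = rigid_rotation_series(1.0)
        rows, cols = np.indices((65, 65))
        s = series.geometry.pixel_spacing
        mask = ChamberMask(np.hypot(cols * s - cx, rows * s - cy) <= 2.0)
        lavd = compute_lavd(series, mask, 0.0, 1.0, 0.05)
        assert lavd.values.max() < 1e-3

    def test_zero_velocity_null(self, rankine_scene):
        series, mask, _, _ = rankine_scene
        zero = VelocitySeries(u=np.zeros_like(series.u), v=np.zeros_like(series.v),
                              times=series.times, geometry=series.geometry)
        lavd = compute_lavd(zero, mask, 0.0, 1.0, 0.05)
        np.testing.assert_allclose(lavd.values, 0.0)

    def test_rankine_closed_form_plateaus(self, rankine_scene):
        series, mask, _, center = rankine_scene
        s = series.geometry.pixel_spacing
        lavd = compute_lavd(series, mask, 0.0, 1.0, 0.02)
        rows, cols = np.indices(mask.pixels.shape)
        r = np.hypot(cols * s - center[0], rows * s - center[1])
        interior = mask.pixels & (r < 1.0 - 2 * s)
        exterior = mask.pixels & (r > 1.0 + 2 * s) & (r < 2.0 - 2 * s)
        np.testing.assert_allclose(lavd.values[interior], 0.75, rtol=0.05)
        np.testing.assert_allclose(lavd.values[exterior], 0.25, rtol=0.05)

    def test_psi_is_half_lavd(self, rankine_scene):
        series, mask, _, _ = rankine_scene
        lavd = compute_lavd(series, mask, 0.0, 0.5, 0.05)
        np.testing.assert_allclose(lavd.psi, 0.5 * lavd.values)

    def test_superposed_solid_body_rotation_invariance(self, rankine_scene):
        series, mask, _, center = rankine_scene
        s = series.geometry.pixel_spacing
        rows, cols = np.indices(mask.pixels.shape)
        x, y = cols * s, rows * s
        omega0 = 0.3
        boosted = VelocitySeries(u=series.u + omega0 * (y - center[1]),
                                 v=series.v - omega0 * (x - center[0]),
                                 times=series.times, geometry=series.geometry)
        base = compute_lavd(series, mask, 0.0, 1.0, 0.02)
        lifted = compute_lavd(boosted, mask, 0.0, 1.0, 0.02)
        r = np.hypot(x - center[0], y - center[1])
        interior = mask.pixels & (r < 1.0 - 2 * s)
        rel = np.abs(lifted.values[interior] - base.values[interior]) / base.values[interior]
        assert rel.max() < 0.02

    def test_window_additivity_on_plateaus(self, rankine_scene):
        series, mask, _, center = rankine_scene
        s = series.geometry.pixel_spacing
        full = compute_lavd(series, mask, 0.0, 1.0, 0.02)
        first = compute_lavd(series, mask, 0.0, 0.5, 0.02)
        second = compute_lavd(series, mask, 0.5, 1.0, 0.02)
        rows, cols = np.indices(mask.pixels.shape)
        r = np.hypot(cols * s - center[0], rows * s - center[1])
        plateau = mask.pixels & ((r < 1.0 - 2 * s) | ((r > 1.0 + 2 * s) & (r < 2.0 - 2 * s)))
        # steady axisymmetric flow: seeds at t=0.5 see the same radii, so the
        # window maps compose additively away from the core-edge discontinuity
        gap = np.abs(first.values + second.values - full.values)[plateau]
        assert gap.max() < 1e-3

    def test_dt_refinement_converged(self, rankine_scene):
        series, mask, _, _ = rankine_scene
        coarse = compute_lavd(series, mask, 0.0, 1.0, 0.02)
        fine = compute_lavd(series, mask, 0.0, 1.0, 0.01)
        assert np.abs(fine.values - coarse.values).max() < 5e-3

    def test_lavd_nonnegative(self, rankine_scene):
        series, mask, _, _ = rankine_scene
        lavd = compute_lavd(series, mask, 0.0, 1.0, 0.05)
        assert lavd.values.min() >= 0.0
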