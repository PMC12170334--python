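import numpy as np
import pytest
from scipy.integrate import simpson

from lashearmap.fields import ScalarField
from lashearmap.mesh import SurfaceMesh
from lashearmap.shear import compute_shear_indices, compute_wssg, surface_scalar_gradient
from lashearmap.traction import TractionSeries, synthesize_traction_series

from conftest import flat_disk_mesh


def series_from(tau, period=1.0):
    tau = np.asarray(tau, dtype=float)
    n = tau.shape[0]
    return TractionSeries(times=np.arange(n) * period / n, tau=tau, period=period)


def random_smooth_series(n_vertices=50, n_samples=64, seed=0, period=1.0):
    """Low-order trigonometric traction signals with known analytic form."""
    rng = np.random.default_rng(seed)
    coef = rng.normal(size=(n_vertices, 3, 5))

    def tau_of_t(t):
        w = 2 * np.pi * t / period
        basis = np.stack(
            [np.ones_like(t), np.cos(w), np.sin(w), np.cos(2 * w), np.sin(2 * w)]
        )
        return np.einsum("vck,kt->tvc", coef, basis)

    t = np.arange(n_samples) * period / n_samples
    return series_from(tau_of_t(t), period), tau_of_t


class TestComputeShearIndices:
    def test_constant_traction_closed_form(self):
        tau = np.tile(np.array([3.0, 4.0, 0.0]), (8, 1, 1))
        idx = compute_shear_indices(series_from(tau))
        assert idx.tawss.values[0] == pytest.approx(5.0)
        assert idx.osi.values[0] == pytest.approx(0.0, abs=1e-15)
        assert idx.rrt.values[0] == pytest.approx(0.2)
        assert idx.holmes.values[0] == pytest.approx(2.5)
        assert idx.ecap.values[0] == pytest.approx(0.0, abs=1e-15)

    def test_full_reversal_symmetry(self):
        tau = np.zeros((16, 1, 3))
        tau[:8, 0, 0] = 1.0
        tau[8:, 0, 0] = -1.0
        idx = compute_shear_indices(series_from(tau))
        assert idx.tawss.values[0] == pytest.approx(1.0)
        assert idx.osi.values[0] == pytest.approx(0.5)
        assert idx.holmes.values[0] == pytest.approx(0.0, abs=1e-12)
        assert not idx.defined[0]  # RRT undefined: zero mean traction
        assert np.isinf(idx.rrt.values[0])

    def test_matches_fine_quadrature_oracle(self):
        """64-sample periodic trapezoid vs 1,024-sample Simpson integration
        of the same analytic series, to 1e-3 relative."""
        series, tau_of_t = random_smooth_series()
        idx = compute_shear_indices(series)
        tfine = np.linspace(0, series.period, 1025)
        tau_fine = tau_of_t(tfine)
        mag = np.linalg.norm(tau_fine, axis=2)
        tawss_o = simpson(mag, x=tfine, axis=0) / series.period
        mean_o = simpson(tau_fine, x=tfine, axis=0) / series.period
        mean_mag_o = np.linalg.norm(mean_o, axis=1)
        osi_o = 0.5 * (1 - mean_mag_o / tawss_o)
        np.testing.assert_allclose(idx.tawss.values, tawss_o, rtol=1e-3)
        np.testing.assert_allclose(idx.osi.values, osi_o, rtol=1e-3, atol=1e-6)
        np.testing.assert_allclose(idx.rrt.values, 1 / mean_mag_o, rtol=1e-3)

    def test_identity_suite_random_series(self):
        series, _ = random_smooth_series(n_vertices=200, seed=3)
        idx = compute_shear_indices(series)
        assert (idx.osi.values >= 0).all() and (idx.osi.values <= 0.5).all()
        np.testing.assert_allclose(
            idx.holmes.values, idx.tawss.values * (0.5 - idx.osi.values), rtol=1e-12
        )
        d = idx.defined
        np.testing.assert_allclose(
            idx.ecap.values[d] * idx.tawss.values[d], idx.osi.values[d], rtol=1e-12
        )
        np.testing.assert_allclose(
            idx.rrt.values[d] * idx.tawss.values[d] * (1 - 2 * idx.osi.values[d]),
            1.0,
            rtol=1e-9,
        )

    def test_osi_invariant_under_rotation(self):
        series, _ = random_smooth_series(seed=4)
        idx = compute_shear_indices(series)
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1]]
        )
        rotated = series_from(series.tau @ R.T)
        idx_r = compute_shear_indices(rotated)
        np.testing.assert_allclose(idx_r.osi.values, idx.osi.values, atol=1e-12)
        np.testing.assert_allclose(idx_r.tawss.values, idx.tawss.values, rtol=1e-12)

    def test_tawss_invariant_under_phase_shift(self):
        series, _ = random_smooth_series(seed=5)
        shifted = series_from(np.roll(series.tau, 13, axis=0))
        a = compute_shear_indices(series)
        b = compute_shear_indices(shifted)
        np.testing.assert_allclose(a.tawss.values, b.tawss.values, rtol=1e-12)

    def test_magnitude_scaling_relations(self):
        series, _ = random_smooth_series(seed=6)
        doubled = series_from(2.0 * series.tau)
        a = compute_shear_indices(series)
        b = compute_shear_indices(doubled)
        d = a.defined
        np.testing.assert_allclose(b.tawss.values, 2 * a.tawss.values, rtol=1e-12)
        np.testing.assert_allclose(b.holmes.values, 2 * a.holmes.values, rtol=1e-12)
        np.testing.assert_allclose(b.rrt.values[d], a.rrt.values[d] / 2, rtol=1e-12)
        np.testing.assert_allclose(b.ecap.values[d], a.ecap.values[d] / 2, rtol=1e-12)
        np.testing.assert_allclose(b.osi.values, a.osi.values, atol=1e-12)

    def test_rejects_short_series(self):
        with pytest.raises(ValueError, match="8 time samples"):
            series_from(np.zeros((4, 1, 3)))


class TestSynthesizeTractionSeries:
    def test_prescribed_tawss_and_osi(self, atrium):
        mag = ScalarField(np.full(atrium.n_vertices, 1.3), "TAWSS", "Pa")
        for osc, osi_target in ((0.0, 0.0), (1.0, 0.5), (0.6, 0.3)):
            series = synthesize_traction_series(atrium, mag, osc, n_samples=32, seed=0)
            idx = compute_shear_indices(series)
            np.testing.assert_allclose(idx.tawss.values, 1.3, rtol=0.02)
            np.testing.assert_allclose(idx.osi.values, osi_target, atol=1.5 / 32)

    def test_traction_tangent_to_surface(self, atrium):
        mag = ScalarField(np.ones(atrium.n_vertices), "TAWSS", "Pa")
        series = synthesize_traction_series(atrium, mag, 0.5, n_samples=16, seed=1)
        n = atrium.vertex_normals()
        dot = np.abs(np.einsum("tvc,vc->tv", series.tau, n))
        norm = np.linalg.norm(series.tau, axis=2)
        assert (dot <= 1e-8 * norm + 1e-30).all()


class TestSurfaceGradient:
    def test_constant_field_zero_gradient(self, atrium):
        g = surface_scalar_gradient(atrium, np.full(atrium.n_vertices, 3.3))
        np.testing.assert_allclose(g, 0.0, atol=1e-10)

    def test_linear_field_exact_on_flat_patch(self):
        disk = flat_disk_mesh(n_rings=6, n_ang=24, radius=10.0)
        g = surface_scalar_gradient(disk, 2.0 * disk.vertices[:, 0])
        np.testing.assert_allclose(g, [[2.0, 0.0, 0.0]] * disk.n_vertices, atol=1e-10)

    def test_convergence_on_sphere(self):
        """Quadratic field f = z^2 on the unit sphere: vertex gradients
        converge to the analytic tangential gradient under refinement."""
        import trimesh

        errs = []
        for sub in (2, 3, 4):
            tm = trimesh.creation.icosphere(subdivisions=sub, radius=1.0)
            mesh = SurfaceMesh(np.array(tm.vertices), np.array(tm.faces))
            z = mesh.vertices[:, 2]
            g = surface_scalar_gradient(mesh, z**2)
            nrm = mesh.vertices  # unit sphere: position is the normal
            analytic = 2 * z[:, None] * (np.eye(3)[2] - z[:, None] * nrm)
            errs.append(np.linalg.norm(g - analytic, axis=1).mean())
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert (orders >= 1.0).all()


class TestWSSG:
    def test_uniform_magnitude_zero_gradient(self, atrium):
        mag = ScalarField(np.full(atrium.n_vertices, 2.0), "TAWSS", "Pa")
        series = synthesize_traction_series(atrium, mag, 0.0, n_samples=16, seed=0)
        wssg = compute_wssg(series, atrium)
        np.testing.assert_allclose(wssg.values, 0.0, atol=1e-9)

    def test_linear_magnitude_aligned_direction(self):
        """||tau|| = x, direction +x on a flat patch: WSSG = 1 Pa/mm."""
        disk = flat_disk_mesh(n_rings=8, n_ang=32, radius=10.0)
        x = disk.vertices[:, 0] + 20.0  # keep magnitude positive
        tau = np.tile(x[:, None] * np.array([1.0, 0, 0]), (8, 1, 1))
        series = series_from(tau)
        wssg = compute_wssg(series, disk)
        interior = np.linalg.norm(disk.vertices[:, :2], axis=1) < 8.0
        np.testing.assert_allclose(wssg.values[interior], 1.0, atol=1e-8)

    def test_orthogonal_direction_zero(self):
        disk = flat_disk_mesh(n_rings=8, n_ang=32, radius=10.0)
        x = disk.vertices[:, 0] + 20.0
        tau = np.tile(x[:, None] * np.array([0.0, 1.0, 0]), (8, 1, 1))
        wssg = compute_wssg(series_from(tau), disk)
        interior = np.linalg.norm(disk.vertices[:, :2], axis=1) < 8.0
        np.testing.assert_allclose(wssg.values[interior], 0.0, atol=1e-8)

    def test_mean_direction_mode_agrees_for_steady_flow(self):
        disk = flat_disk_mesh(n_rings=6, n_ang=24, radius=10.0)
        x = disk.vertices[:, 0] + 20.0
        tau = np.tile(x[:, None] * np.array([1.0, 0, 0]), (8, 1, 1))
        a = compute_wssg(series_from(tau), disk, mode="instantaneous")
        b = compute_wssg(series_from(tau), disk, mode="mean-direction")
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)
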