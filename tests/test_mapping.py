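import numpy as np
import pytest
from scipy import stats as sps

from lashearmap.fields import synthesize_emap_cloud, synthesize_wall_fields
from lashearmap.mapping import (
    RegistrationError,
    RigidTransform,
    icp_align,
    map_fields_to_mesh,
    rbf_interpolate,
)
from lashearmap.pipeline import tawss_pattern


class TestRigidTransform:
    def test_round_trip_inverse(self):
        t = RigidTransform.from_axis_angle((1, 2, 3), 0.8, (4, -1, 2))
        pts = np.random.default_rng(0).random((50, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-12)

    def test_distances_preserved(self):
        t = RigidTransform.from_axis_angle((0, 1, 0), 1.1, (5, 5, 5))
        pts = np.random.default_rng(1).random((30, 3)) * 10
        d0 = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        moved = t.apply(pts)
        d1 = np.linalg.norm(moved[:, None] - moved[None], axis=2)
        np.testing.assert_allclose(d1, d0, rtol=1e-9)

    def test_reflection_rejected(self):
        with pytest.raises(ValueError, match="det"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestICP:
    def test_identity_for_identical_clouds(self):
        pts = np.random.default_rng(2).random((100, 3)) * 20
        res = icp_align(pts, pts)
        assert res.rms < 1e-12
        np.testing.assert_allclose(res.transform.rotation, np.eye(3), atol=1e-9)

    def test_recovers_known_rigid_transform(self):
        """Recovered transform composes with ground truth to identity
        within 1e-6 mm RMS."""
        rng = np.random.default_rng(3)
        pts = rng.random((500, 3)) * 30
        truth = RigidTransform.from_axis_angle((0, 0, 1), np.deg2rad(20), (5, -3, 2))
        moved = truth.apply(pts)
        res = icp_align(moved, pts, max_iter=200)
        back = res.transform.apply(moved)
        rms = np.sqrt(((back - pts) ** 2).sum(axis=1).mean())
        assert rms < 1e-6
        assert res.converged

    def test_collinear_source_rejected(self):
        line = np.outer(np.arange(10), [1.0, 2.0, 3.0])
        with pytest.raises(RegistrationError, match="collinear"):
            icp_align(line, np.random.default_rng(0).random((20, 3)))

    def test_rms_non_increasing(self, atrium):
        pose = RigidTransform.from_axis_angle((1, 0, 0), 0.15, (3, 1, -2))
        cloud = synthesize_emap_cloud(atrium, 800, transform=pose, jitter_sd=0.3, seed=4)
        res = icp_align(cloud.points, atrium.vertices)
        assert (np.diff(res.rms_history) <= 1e-9).all()


class TestRBF:
    def test_interpolates_site_values(self):
        rng = np.random.default_rng(5)
        sites = rng.random((80, 3)) * 10
        vals = rng.random(80)
        out = rbf_interpolate(sites, vals, sites, smoothing=0.0)
        np.testing.assert_allclose(out, vals, rtol=1e-8, atol=1e-8)

    @pytest.mark.parametrize("kernel", ["thin-plate", "linear", "gaussian"])
    def test_linear_field_reproduced(self, kernel):
        rng = np.random.default_rng(6)
        sites = rng.random((120, 3)) * 10
        f = lambda p: 2 * p[:, 0] - p[:, 1] + 3.0
        queries = rng.random((60, 3)) * 10
        out = rbf_interpolate(sites, f(sites), queries, kernel=kernel, smoothing=0.0)
        np.testing.assert_allclose(out, f(queries), rtol=1e-6, atol=1e-6)

    def test_constant_values(self):
        rng = np.random.default_rng(7)
        sites = rng.random((50, 3))
        out = rbf_interpolate(sites, np.full(50, 2.5), rng.random((20, 3)))
        np.testing.assert_allclose(out, 2.5, atol=1e-8)

    def test_duplicate_sites_without_smoothing_rejected(self):
        sites = np.random.default_rng(8).random((20, 3))
        sites[5] = sites[6]
        with pytest.raises(ValueError, match="smoothing"):
            rbf_interpolate(sites, np.arange(20.0), sites[:3], smoothing=0.0)

    def test_subsampling_warns(self):
        rng = np.random.default_rng(9)
        sites = rng.random((300, 3)) * 5
        with pytest.warns(UserWarning, match="subsampled"):
            rbf_interpolate(sites, rng.random(300), sites[:10], max_sites=100, seed=0)

    def test_linear_kernel_extrema_bounded_inside_hull(self):
        """Monotone sanity: hull-interior queries stay within the source
        value range for the linear kernel (thin-plate is only logged)."""
        rng = np.random.default_rng(1)
        sites = rng.random((200, 3))
        vals = rng.random(200)
        queries = 0.2 + 0.6 * rng.random((500, 3))
        out = rbf_interpolate(sites, vals, queries, kernel="linear", smoothing=0.0)
        assert out.min() >= vals.min() - 1e-9
        assert out.max() <= vals.max() + 1e-9


class TestMapFieldsToMesh:
    def test_self_mapping_recovers_field(self, atrium_medium):
        """Cloud sampled from the mesh's own BV field at identity pose maps
        back with r > 0.99 (field resolvable at the sampling density)."""
        tawss = tawss_pattern(atrium_medium, 0)
        bv, _ = synthesize_wall_fields(atrium_medium, tawss, noise_length=20.0, seed=1)
        cloud = synthesize_emap_cloud(
            atrium_medium, 4000, jitter_sd=0.0, bv_field=bv, seed=2
        )
        mapped, _ = map_fields_to_mesh(
            atrium_medium, emap_points=cloud.points, emap_bv=cloud.bv
        )
        r, _ = sps.pearsonr(bv.values, mapped.values)
        assert r > 0.99

    def test_recovery_after_known_rigid_displacement(self, atrium_medium):
        tawss = tawss_pattern(atrium_medium, 0)
        bv, _ = synthesize_wall_fields(atrium_medium, tawss, noise_length=20.0, seed=1)
        pose = RigidTransform.from_axis_angle((0, 0, 1), np.deg2rad(15), (4, -2, 3))
        cloud = synthesize_emap_cloud(
            atrium_medium, 4000, transform=pose, jitter_sd=0.0, bv_field=bv, seed=2
        )
        mapped, _ = map_fields_to_mesh(
            atrium_medium, emap_points=cloud.points, emap_bv=cloud.bv
        )
        r, _ = sps.pearsonr(bv.values, mapped.values)
        assert r > 0.99

    def test_sparse_cloud_warns_and_completes(self, atrium):
        pts = atrium.vertices[:10] + 0.01
        with pytest.warns(UserWarning, match="sites"):
            mapped, _ = map_fields_to_mesh(atrium, emap_points=pts, emap_bv=np.arange(10.0))
        assert np.isfinite(mapped.values).all()

    def test_correlation_survives_mapping(self, atrium_fine):
        """The injected TAWSS-BV coupling survives the ICP + RBF chain with
        |delta r| < 0.05 at clinical point density."""
        tawss = tawss_pattern(atrium_fine, 4)
        bv, _ = synthesize_wall_fields(atrium_fine, tawss, seed=14)
        pose = RigidTransform.from_axis_angle((0, 1, 0), 0.2, (3, 2, -1))
        cloud = synthesize_emap_cloud(
            atrium_fine, 8000, transform=pose, jitter_sd=0.5, bv_field=bv, seed=24
        )
        mapped, _ = map_fields_to_mesh(atrium_fine, emap_points=cloud.points, emap_bv=cloud.bv)
        r_before, _ = sps.pearsonr(tawss.values, bv.values)
        r_after, _ = sps.pearsonr(tawss.values, mapped.values)
        assert abs(r_after - r_before) < 0.05
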