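import numpy as np
import pandas as pd
import pytest

from lashearmap.fields import ScalarField
from lashearmap.mesh import LABELS, MeshTopologyError
from lashearmap.template import Template2D, build_template, template_from_unfolded
from lashearmap.unfolding import (
    assign_regions,
    rasterize_map,
    regional_means,
    register_to_atlas,
    unfold_to_2d,
)

from conftest import flat_disk_mesh


class TestRegisterToAtlas:
    def test_self_registration_identity(self, atrium):
        reg = register_to_atlas(atrium, atrium)
        assert reg.scale == pytest.approx(1.0, abs=1e-9)
        assert max(d for _, _, d in reg.landmark_pairs.values()) < 1e-9

    def test_recovers_isotropic_scale(self, atrium):
        atlas = atrium.copy()
        atlas.vertices = atlas.vertices * 1.3
        reg = register_to_atlas(atrium, atlas)
        assert reg.scale == pytest.approx(1.3, abs=1e-6)

    def test_missing_label_class_named_in_error(self, atrium):
        broken = atrium.copy()
        broken.vertex_labels[broken.vertex_labels == LABELS["LIPV"]] = LABELS["body"]
        with pytest.raises(MeshTopologyError, match="LIPV"):
            register_to_atlas(broken, atrium)


class TestUnfoldTo2D:
    def test_planar_disk_maps_to_identity_up_to_rotation(self):
        disk = flat_disk_mesh(n_rings=10, n_ang=32, radius=1.0)
        unf = unfold_to_2d(disk, build_template())
        assert unf.flip_count == 0
        r3 = np.linalg.norm(disk.vertices[:, :2], axis=1)
        r2 = np.linalg.norm(unf.uv, axis=1)
        np.testing.assert_allclose(r2, r3, atol=1e-9)
        ang = np.arctan2(unf.uv[1:, 1], unf.uv[1:, 0]) - np.arctan2(
            disk.vertices[1:, 1], disk.vertices[1:, 0]
        )
        ang = np.mod(ang + np.pi, 2 * np.pi) - np.pi
        assert ang.max() - ang.min() < 1e-9

    def test_atrium_unfolds_flip_free_with_pinned_rim(self, clipped):
        unf = unfold_to_2d(clipped, build_template())
        assert unf.flip_count == 0
        assert unf.boundary_residual < 1e-6

    def test_missing_mitral_rim_is_topology_error(self, clipped):
        broken = clipped.copy()
        broken.vertex_labels[broken.vertex_labels == LABELS["mitral_rim"]] = LABELS["floor"]
        with pytest.raises(MeshTopologyError, match="mitral"):
            unfold_to_2d(broken, build_template())

    def test_matched_perimeter_reduces_area_distortion(self, clipped):
        """Scaling the template perimeter to the mitral-rim length lowers the
        mean absolute log area ratio between 2D and 3D triangles."""
        rim = next(
            lp
            for lp in clipped.boundary_loops()
            if (clipped.vertex_labels[lp] == LABELS["mitral_rim"]).mean() > 0.5
        )
        pts = clipped.vertices[rim]
        rim_len = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum()

        def distortion(radius):
            unf = unfold_to_2d(clipped, build_template(radius=radius))
            tri = unf.meta["triangles"]
            p = unf.uv[tri]
            a2 = 0.5 * np.abs(
                (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
            )
            a3 = clipped.triangle_areas()
            ok = (a2 > 0) & (a3 > 0)
            return np.abs(np.log(a2[ok] / a3[ok])).mean()

        assert distortion(rim_len / (2 * np.pi)) < distortion(1.0)


class TestAssignRegions:
    def test_exactly_24_regions_present(self, unfolded):
        unf, _ = unfolded
        present = np.unique(unf.region[unf.region > 0])
        assert len(present) == 24

    def test_every_vertex_labeled_once(self, unfolded):
        unf, _ = unfolded
        assert (unf.region >= 1).all() and (unf.region <= 24).all()
        counts = np.bincount(unf.region, minlength=25)[1:]
        assert counts.sum() == len(unf.region)

    def test_pv_rim_vertices_in_designated_regions(self, clipped, unfolded):
        unf, tpl = unfolded
        names = tpl.region_names()
        for rid in (1, 2, 3, 4):
            sel = clipped.vertex_labels == LABELS[names[rid]]
            assert (unf.region[sel] == rid).all(), names[rid]

    def test_template_json_round_trip(self, unfolded):
        _, tpl = unfolded
        back = Template2D.from_json(tpl.to_json())
        assert back.region_names() == tpl.region_names()
        for (rid, _, g1), (_, _, g2) in zip(tpl.regions, back.regions):
            assert g1.symmetric_difference(g2).area < 1e-9


class TestRegionalMeans:
    def test_constant_field_all_normalized_to_one(self, unfolded):
        unf, _ = unfolded
        df = regional_means(ScalarField(np.full(len(unf.uv), 3.0), "c"), unf)
        filled = df[df["count"] > 0]
        np.testing.assert_allclose(filled["mean"], 3.0)
        np.testing.assert_allclose(filled["normalized_mean"], 1.0)

    def test_matches_group_by_oracle(self, unfolded):
        unf, _ = unfolded
        rng = np.random.default_rng(0)
        vals = rng.random(len(unf.uv))
        df = regional_means(ScalarField(vals, "x"), unf).set_index("region")
        for rid in range(1, 25):
            sel = unf.region == rid
            if sel.any():
                assert df.loc[rid, "mean"] == pytest.approx(vals[sel].mean(), abs=1e-12)
        vmax = df["mean"].max()
        np.testing.assert_allclose(df["normalized_mean"], df["mean"] / vmax, atol=1e-12)

    def test_single_dominant_region_normalizes_to_one(self, unfolded):
        unf, _ = unfolded
        vals = np.ones(len(unf.uv))
        vals[unf.region == 9] = 10.0
        df = regional_means(ScalarField(vals, "x"), unf).set_index("region")
        assert df.loc[9, "normalized_mean"] == pytest.approx(1.0)
        others = df.drop(9).dropna()
        assert (others["normalized_mean"] < 1.0).all()

    def test_permutation_invariant(self, unfolded):
        unf, _ = unfolded
        rng = np.random.default_rng(1)
        vals = rng.random(len(unf.uv))
        perm = rng.permutation(len(vals))
        from lashearmap.unfolding import UnfoldedMap

        shuffled = UnfoldedMap(uv=unf.uv[perm], region=unf.region[perm])
        a = regional_means(ScalarField(vals, "x"), unf)
        b = regional_means(ScalarField(vals[perm], "x"), shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_undefined_values_excluded(self, unfolded):
        unf, _ = unfolded
        vals = np.ones(len(unf.uv))
        vals[unf.region == 1] = np.nan
        df = regional_means(ScalarField(vals, "x"), unf).set_index("region")
        assert np.isnan(df.loc[1, "mean"])
        assert df.loc[1, "count"] == 0


class TestRasterizeMap:
    def test_constant_field_uniform_pixels(self, unfolded):
        unf, _ = unfolded
        img, _, _ = rasterize_map(unf, ScalarField(np.full(len(unf.uv), 2.0), "c"), 128)
        covered = img[np.isfinite(img)]
        np.testing.assert_allclose(covered, 2.0, atol=1e-12)

    def test_coverage_stable_under_refinement(self, unfolded):
        unf, _ = unfolded
        field = ScalarField(np.ones(len(unf.uv)), "c")
        f1 = np.isfinite(rasterize_map(unf, field, 128)[0]).mean()
        f2 = np.isfinite(rasterize_map(unf, field, 256)[0]).mean()
        assert abs(f1 - f2) < 0.02

    def test_linear_field_exact(self, unfolded):
        unf, _ = unfolded
        vals = 2.0 * unf.uv[:, 0] - 0.5 * unf.uv[:, 1] + 1.0
        img, extent, _ = rasterize_map(unf, ScalarField(vals, "lin"), 64)
        xs = np.linspace(extent[0], extent[1], 64)
        ys = np.linspace(extent[2], extent[3], 64)
        gx, gy = np.meshgrid(xs, ys)
        expect = 2.0 * gx - 0.5 * gy + 1.0
        ok = np.isfinite(img)
        np.testing.assert_allclose(img[ok], expect[ok], atol=1e-6)
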