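"""Atlas registration and 2D unfolding of the atrial wall.

The clipped atrium is a topological disk with holes (PV rims and the
appendage mouth are free holes; the mitral rim is the outer boundary).  The
unfolding is a harmonic parameterization with mean-value weights: interior
vertices solve the discrete Laplace equation while the mitral rim is pinned
to the template perimeter by arc-length proportion, anchored at the septal
side.  Mean-value weights are positive, so with the convex perimeter the
embedding is flip-free; the flip count is still computed and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import spsolve

from .fields import ScalarField
from .mapping import RigidTransform, icp_align
from .mesh import LABELS, PV_LABELS, MeshTopologyError, SurfaceMesh
from .template import Template2D, point_region_ids, snap_to_regions


@dataclass
class UnfoldedMap:
    uv: np.ndarray  # (N, 2) template coordinates
    region: np.ndarray = None  # (N,) in 1..24, 0 = unassigned
    flip_count: int = 0
    boundary_residual: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.uv = np.asarray(self.uv, dtype=float)
        if self.region is None:
            self.region = np.zeros(len(self.uv), dtype=np.int64)


@dataclass
class AtlasRegistration:
    transform: RigidTransform
    scale: float
    rms: float
    landmark_pairs: dict  # label -> (moved mesh landmark, atlas landmark, distance mm)


_LANDMARK_CLASSES = list(PV_LABELS) + ["appendage", "mitral_rim"]


def register_to_atlas(mesh: SurfaceMesh, atlas: SurfaceMesh) -> AtlasRegistration:
    """Similarity alignment (ICP with isotropic scale) plus label-wise
    landmark matching of the PV ostia, appendage and mitral rim.

    The initial scale is seeded from the RMS-radius ratio of the two vertex
    sets, which makes the similarity ICP exact for meshes that differ by a
    pure similarity.
    """
    for m, who in ((mesh, "mesh"), (atlas, "atlas")):
        missing = [c for c in _LANDMARK_CLASSES if not (m.vertex_labels == LABELS[c]).any()]
        if missing:
            raise MeshTopologyError(f"{who} is missing label class(es): {missing}")

    src, tgt = mesh.vertices, atlas.vertices
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    s0 = float(
        np.sqrt(((tgt - tc) ** 2).sum() / len(tgt))
        / np.sqrt(((src - sc) ** 2).sum() / len(src))
    )
    pre = s0 * (src - sc) + tc
    icp = icp_align(pre, tgt, with_scale=True, max_iter=200, rel_tol=1e-12)
    scale = s0 * icp.scale

    def move(points):
        return icp.transform.apply(s0 * (points - sc) + tc)

    pairs = {}
    for cls in _LANDMARK_CLASSES:
        m_lm = move(mesh.vertices[mesh.vertex_labels == LABELS[cls]].mean(axis=0)[None])[0]
        a_lm = atlas.vertices[atlas.vertex_labels == LABELS[cls]].mean(axis=0)
        pairs[cls] = (m_lm, a_lm, float(np.linalg.norm(m_lm - a_lm)))
    return AtlasRegistration(
        transform=icp.transform, scale=scale, rms=icp.rms, landmark_pairs=pairs
    )


# ----------------------------------------------------------------------
def _mean_value_weights(mesh: SurfaceMesh):
    """Sparse symmetric-pattern matrix of mean-value weights w_ij > 0."""
    tri = mesh.triangles
    p = mesh.vertices
    rows, cols, vals = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        i, j, k = tri[:, a], tri[:, b], tri[:, c]
        e1 = p[j] - p[i]
        e2 = p[k] - p[i]
        l1 = np.linalg.norm(e1, axis=1)
        l2 = np.linalg.norm(e2, axis=1)
        cosang = np.clip(np.einsum("ij,ij->i", e1, e2) / (l1 * l2), -1.0, 1.0)
        t = np.tan(0.5 * np.arccos(cosang))
        # the angle at i flanks both edges (i,j) and (i,k)
        rows += [i, i]
        cols += [j, k]
        vals += [t / l1, t / l2]
    n = mesh.n_vertices
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _pin_rim_to_perimeter(mesh: SurfaceMesh, rim: np.ndarray, template: Template2D):
    """Arc-length-proportional positions of the mitral rim on the perimeter,
    anchored at the rim vertex nearest the septal wall, following the rim's
    own (face-induced) orientation."""
    septal = mesh.vertices[mesh.vertex_labels == LABELS["septal"]]
    anchor_pos = septal.mean(axis=0) if len(septal) else mesh.vertices.mean(axis=0)
    start = int(np.argmin(np.linalg.norm(mesh.vertices[rim] - anchor_pos, axis=1)))
    rim = np.roll(rim, -start)
    pts = mesh.vertices[rim]
    seg = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg[:-1])]) / seg.sum()
    ring = shapely.LineString(template.perimeter.exterior.coords)
    uv = np.array(
        [ring.interpolate(si * ring.length).coords[0] for si in s]
    )
    return rim, uv


def _flip_count(uv: np.ndarray, triangles: np.ndarray) -> tuple[int, int]:
    """(flips, degenerate) by signed 2D area.

    A flip is a minority-orientation triangle whose area is above numerical
    noise (1e-12 of the largest triangle); slivers below that (collinear
    rim triangles mapped to the boundary of a free hole) are degenerate,
    not inverted.
    """
    p = uv[triangles]
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    eps = 1e-12 * np.abs(cross).max()
    pos = int((cross > eps).sum())
    neg = int((cross < -eps).sum())
    return min(pos, neg), int((np.abs(cross) <= eps).sum())


def unfold_to_2d(mesh: SurfaceMesh, template: Template2D) -> UnfoldedMap:
    """Harmonic unfolding with the mitral rim pinned to the perimeter.

    Requires the standardized mesh (PVs clipped); PV rims and the appendage
    are free holes.  Raises a topology error when no mitral rim loop exists.
    """
    loops = mesh.boundary_loops()
    rim_loop = None
    for lp in loops:
        labs = mesh.vertex_labels[lp]
        if (labs == LABELS["mitral_rim"]).mean() > 0.5:
            rim_loop = lp
            break
    if rim_loop is None:
        raise MeshTopologyError(
            "no mitral rim boundary loop found "
            f"(chi = {mesh.euler_characteristic()}, loops = {len(loops)})"
        )

    rim, rim_uv = _pin_rim_to_perimeter(mesh, rim_loop, template)
    n = mesh.n_vertices
    W = _mean_value_weights(mesh)
    diag = np.asarray(W.sum(axis=1)).ravel()
    L = coo_matrix(
        (diag, (np.arange(n), np.arange(n))), shape=(n, n)
    ).tocsr() - W

    fixed = np.zeros(n, dtype=bool)
    fixed[rim] = True
    free = ~fixed
    uv = np.zeros((n, 2))
    uv[rim] = rim_uv
    A = L[free][:, free]
    B = L[free][:, fixed]
    rhs = -B @ uv[fixed]
    uv[free] = spsolve(A.tocsc(), rhs)

    # orientation: harmonic images follow the imposed rim direction; count
    # the minority orientation as flips
    flips, degenerate = _flip_count(uv, mesh.triangles)
    ring = shapely.LineString(template.perimeter.exterior.coords)
    residual = max(ring.distance(shapely.Point(q)) for q in uv[rim])
    return UnfoldedMap(
        uv=uv,
        flip_count=flips,
        boundary_residual=float(residual),
        meta={
            "rim_size": len(rim),
            "n_holes": len(loops) - 1,
            "degenerate_triangles": degenerate,
            "triangles": mesh.triangles.copy(),
        },
    )


def assign_regions(
    unfolded: UnfoldedMap, template: Template2D, vertex_labels=None
) -> UnfoldedMap:
    """Label every vertex with one of the 24 template regions.

    Vertices not covered by any region polygon (numerical slivers along
    shared edges) are snapped to the nearest region; the count is recorded
    in the map metadata.
    """
    ids = point_region_ids(template, unfolded.uv)
    ids, snapped = snap_to_regions(template, unfolded.uv, ids)
    unfolded.region = ids
    unfolded.meta["snapped_vertices"] = snapped
    unfolded.meta["region_names"] = template.region_names()
    return unfolded


def regional_means(field_: ScalarField, unfolded: UnfoldedMap) -> pd.DataFrame:
    """Mean and normalized mean (x_bar_i / max_i x_bar_i) per region.

    Undefined (non-finite) vertex values are excluded; empty regions get NaN
    means and do not participate in the normalizing maximum.
    """
    if unfolded.region.max() == 0:
        raise ValueError("regions not assigned; call assign_regions first")
    vals = np.asarray(field_.values, dtype=float)
    ok = np.isfinite(vals)
    df = pd.DataFrame({"region": unfolded.region[ok], "value": vals[ok]})
    g = df.groupby("region")["value"].agg(["mean", "count"])
    out = g.reindex(range(1, 25))
    out["count"] = out["count"].fillna(0).astype(int)
    vmax = out["mean"].max()
    out["normalized_mean"] = out["mean"] / vmax if np.isfinite(vmax) and vmax != 0 else np.nan
    out.index.name = "region"
    return out.reset_index()


def rasterize_map(
    unfolded: UnfoldedMap, field_: ScalarField, resolution: int = 256
):
    """Rasterize a vertex field over the unfolded map.

    Barycentric (linear) interpolation inside mapped triangles via
    matplotlib's triangular interpolator; pixels outside the atrium are NaN
    (transparent).  Returns (image, extent, colorbar metadata).
    """
    import matplotlib.tri as mtri

    uv = unfolded.uv
    tri = unfolded.meta.get("triangles")
    if tri is None:
        raise ValueError("unfolded.meta['triangles'] required for rasterization")
    lo = uv.min(axis=0)
    hi = uv.max(axis=0)
    xs = np.linspace(lo[0], hi[0], resolution)
    ys = np.linspace(lo[1], hi[1], resolution)
    gx, gy = np.meshgrid(xs, ys)
    vals = np.asarray(field_.values, dtype=float)
    triang = mtri.Triangulation(uv[:, 0], uv[:, 1], tri)
    interp = mtri.LinearTriInterpolator(triang, vals)
    img = interp(gx, gy).filled(np.nan)
    extent = (lo[0], hi[0], lo[1], hi[1])
    finite = vals[np.isfinite(vals)]
    meta = {
        "vmin": float(finite.min()) if len(finite) else np.nan,
        "vmax": float(finite.max()) if len(finite) else np.nan,
        "name": field_.name,
        "units": field_.units,
    }
    return img, extent, meta
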