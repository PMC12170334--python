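"""Idealized left-atrial geometry and its standardization.

The synthetic atrium is a parametric stand-in for a patient-specific
anatomical model: an ellipsoidal chamber with four pulmonary-vein (PV) tubes
opening on the posterior wall, a tapered appendage pouch and an open mitral
orifice.  Standardization follows the conventions of image-based hemodynamic
pipelines: straight flow extensions of ten equivalent diameters at every open
orifice (so imposed velocity profiles develop before entering the chamber),
and PV truncation to a fixed residual length before unfolding.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh import (
    LABELS,
    PV_LABELS,
    MeshTopologyError,
    SurfaceMesh,
    loop_best_fit_plane,
    loop_plane_area,
)


class GeometryError(ValueError):
    """Degenerate or inconsistent geometric input."""


# Outward unit directions (before semi-axis scaling) of the anatomical
# features on the chamber.  Posterior wall is y < 0; left side is x < 0.
_FEATURE_DIRECTIONS = {
    "LSPV": (-0.72, -0.52, 0.46),
    "LIPV": (-0.80, -0.52, -0.29),
    "RSPV": (0.72, -0.52, 0.46),
    "RIPV": (0.80, -0.52, -0.29),
    "appendage": (-0.62, 0.62, 0.48),
    "mitral_rim": (0.0, 0.28, -0.96),
}


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _plane_basis(normal):
    n = _unit(normal)
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(n, a))
    e2 = np.cross(n, e1)
    return e1, e2


def _directed_loop_near(mesh: SurfaceMesh, point) -> np.ndarray:
    """Boundary loop (directed as in faces) whose centroid is nearest to point."""
    loops = mesh.boundary_loops()
    if not loops:
        raise MeshTopologyError("expected an open boundary loop, found none")
    cents = [mesh.vertices[lp].mean(axis=0) for lp in loops]
    i = int(np.argmin([np.linalg.norm(c - point) for c in cents]))
    return loops[i]


def _cut_hole(mesh: SurfaceMesh, p0, direction, radius) -> SurfaceMesh:
    """Open a hole by removing vertices within ``radius`` of the outward axis."""
    d = _unit(direction)
    rel = mesh.vertices - p0
    axial = rel @ d
    radial = np.linalg.norm(rel - np.outer(axial, d), axis=1)
    remove = (radial < radius) & (axial > -radius)
    if not remove.any():
        raise GeometryError("hole cut removed no vertices; resolution too coarse")
    return mesh.submesh_from_vertex_mask(~remove)


def _stitch_tube(
    mesh: SurfaceMesh,
    loop: np.ndarray,
    center,
    direction,
    ring_radii,
    ring_offsets,
    label: int,
    blend_rings: int,
    cap: bool = False,
):
    """Attach a tube of morphing rings to a directed boundary loop.

    ``loop`` must be directed as the boundary edges occur in the existing
    faces, which fixes the winding of the new strip triangles so the result
    stays consistently oriented.
    """
    d = _unit(direction)
    e1, e2 = _plane_basis(d)
    pts = mesh.vertices[loop]
    rel = pts - center
    t_axial = rel @ d
    x, y = rel @ e1, rel @ e2
    theta = np.arctan2(y, x)
    rho = np.hypot(x, y)

    verts = [mesh.vertices]
    labels = [mesh.vertex_labels]
    faces = [mesh.triangles]
    prev = loop
    n = len(loop)
    nv = mesh.n_vertices
    for j, (rr, off) in enumerate(zip(ring_radii, ring_offsets), start=1):
        s = min(1.0, j / max(blend_rings, 1))
        r_j = (1.0 - s) * rho + s * rr
        ax_j = (1.0 - s) * t_axial + off
        ring = (
            center
            + np.outer(ax_j, d)
            + r_j[:, None] * (np.outer(np.cos(theta), e1) + np.outer(np.sin(theta), e2))
        )
        idx = np.arange(nv, nv + n)
        nv += n
        verts.append(ring)
        labels.append(np.full(n, label, dtype=np.int64))
        a, b = prev, idx
        ip1 = np.roll(np.arange(n), -1)
        tri1 = np.column_stack([a[ip1], a, b])
        tri2 = np.column_stack([a[ip1], b, b[ip1]])
        faces.append(np.concatenate([tri1, tri2]))
        prev = idx
    if cap:
        apex = (
            center
            + d * (ring_offsets[-1] + max(ring_radii[-1], 1e-9))
        )
        verts.append(apex[None, :])
        labels.append(np.array([label], dtype=np.int64))
        ip1 = np.roll(np.arange(n), -1)
        faces.append(np.column_stack([prev[ip1], prev, np.full(n, nv)]))
        nv += 1
    return SurfaceMesh(
        vertices=np.concatenate(verts),
        triangles=np.concatenate(faces),
        vertex_labels=np.concatenate(labels),
    )


def _sector_labels(mesh: SurfaceMesh, semi_axes) -> None:
    """Assign body-wall sector labels (roof/posterior/anterior/lateral/septal/floor)
    to vertices still carrying the generic body label, by chamber direction."""
    body = mesh.vertex_labels == LABELS["body"]
    w = mesh.vertices[body] / np.asarray(semi_axes, dtype=float)
    norm = np.linalg.norm(w, axis=1)
    norm[norm == 0] = 1.0
    w = w / norm[:, None]
    # equatorial band split by azimuth; a transitional ring below the roof
    # keeps the generic body class populated
    az = np.degrees(np.arctan2(w[:, 1], w[:, 0])) % 360.0
    lab = np.full(len(w), LABELS["septal"], dtype=np.int64)
    lab[(az >= 45) & (az < 135)] = LABELS["anterior"]
    lab[(az >= 135) & (az < 225)] = LABELS["lateral"]
    lab[(az >= 225) & (az < 315)] = LABELS["posterior"]
    lab[(w[:, 2] > 0.45) & (w[:, 2] <= 0.62)] = LABELS["body"]
    lab[w[:, 2] > 0.62] = LABELS["roof"]
    lab[w[:, 2] < -0.45] = LABELS["floor"]
    mesh.vertex_labels[body] = lab


def build_idealized_atrium(
    body_semi_axes=(30.0, 25.0, 24.0),
    pv_radius: float = 6.0,
    pv_length: float = 30.0,
    appendage_scale: float = 1.0,
    resolution: float = 2.0,
    seed: int = 0,
) -> SurfaceMesh:
    """Generate the idealized labeled left atrium.

    Returns a genus-0 surface with exactly five boundary loops: the four PV
    tubes open at their distal ends and the mitral orifice.  The appendage is
    a closed pouch.  ``resolution`` is the target edge length in mm.

    Raises
    ------
    GeometryError
        If ``resolution`` is coarser than ``pv_radius`` (the tubes could not
        be resolved) or ``appendage_scale <= 0``.
    """
    semi_axes = np.asarray(body_semi_axes, dtype=float)
    if (semi_axes <= 0).any() or pv_radius <= 0 or resolution <= 0 or pv_length <= 0:
        raise GeometryError("semi-axes, pv_radius, pv_length and resolution must be > 0")
    if appendage_scale <= 0:
        raise GeometryError("appendage_scale must be > 0 (the pouch would be degenerate)")
    if resolution > pv_radius:
        raise GeometryError(
            f"resolution {resolution} mm is coarser than pv_radius {pv_radius} mm"
        )

    mean_r = float(semi_axes.mean())
    subdiv = int(np.clip(np.ceil(np.log2(1.0515 * mean_r / resolution)), 2, 6))
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    mesh = SurfaceMesh(
        vertices=np.array(ico.vertices) * semi_axes,
        triangles=np.array(ico.faces),
        vertex_labels=np.full(len(ico.vertices), LABELS["body"], dtype=np.int64),
    )

    ring_h = resolution
    mitral_radius = 13.0
    app_radius = 8.0 * appendage_scale
    features = [
        (name, pv_radius) for name in PV_LABELS
    ] + [("appendage", app_radius), ("mitral_rim", mitral_radius)]

    for name, r_cut in features:
        d = _unit(_FEATURE_DIRECTIONS[name])
        # surface point of the ellipsoid along d
        scale = 1.0 / np.sqrt(((d / semi_axes) ** 2).sum())
        p0 = d * scale
        mesh = _cut_hole(mesh, p0, d, r_cut)
        loop = _directed_loop_near(mesh, p0)
        center = mesh.vertices[loop].mean(axis=0)
        if name in PV_LABELS:
            m = max(3, int(np.ceil(pv_length / ring_h)))
            offsets = np.linspace(pv_length / m, pv_length, m)
            radii = np.full(m, pv_radius)
            blend = int(np.clip(np.ceil(pv_radius / ring_h), 2, m))
            mesh.vertex_labels[loop] = LABELS[name]  # ostium curve
            mesh = _stitch_tube(
                mesh, loop, center, d, radii, offsets, LABELS[name], blend
            )
        elif name == "appendage":
            length = 25.0 * appendage_scale
            m = max(4, int(np.ceil(length / ring_h)))
            offsets = np.linspace(length / m, length, m)
            taper = np.linspace(1.0, 0.35, m)
            radii = app_radius * taper
            blend = int(np.clip(np.ceil(app_radius / ring_h), 2, m))
            mesh.vertex_labels[loop] = LABELS["appendage"]
            mesh = _stitch_tube(
                mesh, loop, center, d, radii, offsets, LABELS["appendage"], blend, cap=True
            )
        else:  # mitral collar: short tube ending in a clean circular rim
            m = 3
            length = 3.0
            offsets = np.linspace(length / m, length, m)
            radii = np.full(m, mitral_radius)
            mesh = _stitch_tube(
                mesh, loop, center, d, radii, offsets, LABELS["floor"], blend_rings=2
            )
            rim = _directed_loop_near(mesh, center + d * length)
            mesh.vertex_labels[rim] = LABELS["mitral_rim"]

    _sector_labels(mesh, semi_axes)
    mesh.check_manifold()

    loops = mesh.boundary_loops()
    if len(loops) != 5:
        raise GeometryError(f"expected 5 boundary loops, built {len(loops)}")
    if mesh.euler_characteristic() != 2 - 5:
        raise GeometryError("atrium is not genus 0 with 5 boundary loops")
    missing = set(LABELS) - mesh.labels_present()
    if missing:
        raise GeometryError(f"empty label classes: {sorted(missing)}")
    return mesh


def orifice_equivalent_diameter(mesh: SurfaceMesh, loop: np.ndarray) -> float:
    """Hydraulic equivalent diameter d_eq = sqrt(4 A / pi) of a boundary loop,
    with A the loop area projected on its best-fit plane."""
    area = loop_plane_area(mesh.vertices[loop])
    return float(np.sqrt(4.0 * area / np.pi))


def add_flow_extensions(mesh: SurfaceMesh, factor: float = 10.0) -> SurfaceMesh:
    """Append a straight tube of length ``factor`` x equivalent diameter to
    every open orifice, along the mean outward boundary normal.

    Extension vertices inherit the parent orifice label.  ``factor = 0``
    returns an unchanged copy.
    """
    if factor < 0:
        raise GeometryError("extension factor must be >= 0")
    out = mesh.copy()
    if factor == 0:
        return out
    loops = out.boundary_loops()
    if not loops:
        raise GeometryError("mesh has no open boundary loop to extend")
    centroid = out.vertices.mean(axis=0)
    for loop in loops:
        pts = out.vertices[loop]
        c, n = loop_best_fit_plane(pts)
        if n @ (c - centroid) < 0:
            n = -n
        area = loop_plane_area(pts)
        d_eq = np.sqrt(4.0 * area / np.pi)
        oop = np.abs((pts - c) @ n)
        if oop.max() > 0.15 * np.sqrt(area):
            warnings.warn(
                "non-planar orifice; using projected-plane area for d_eq",
                stacklevel=2,
            )
        length = factor * d_eq
        edge = np.linalg.norm(pts - np.roll(pts, -1, axis=0), axis=1).mean()
        m = max(2, int(np.ceil(length / edge)))
        offsets = np.linspace(length / m, length, m)
        label = int(np.bincount(out.vertex_labels[loop]).argmax())
        # straight prism: keep the loop's own cross-section (blend disabled)
        rel = pts - c
        rho = np.linalg.norm(rel - np.outer(rel @ n, n), axis=1)
        loop_now = _directed_loop_near(out, c)
        out = _stitch_tube(
            out, loop_now, c, n,
            ring_radii=[rho.mean()] * m, ring_offsets=offsets,
            label=label, blend_rings=10 ** 9,
        )
    return out


def _pv_geodesics(mesh: SurfaceMesh, label: int):
    """Multi-source Dijkstra distances from the ostium curve over the PV tube.

    The ostium sources are PV-labeled vertices adjacent to a differently
    labeled vertex; edges are restricted to the PV vertex subset so paths
    cannot shortcut through the chamber body.
    """
    pv = mesh.vertex_labels == label
    idx = np.where(pv)[0]
    if len(idx) == 0:
        raise GeometryError(f"no vertices carry PV label {label}")
    e = mesh.undirected_edges()
    touches_out = np.zeros(mesh.n_vertices, dtype=bool)
    mixed = pv[e[:, 0]] != pv[e[:, 1]]
    touches_out[e[mixed][:, 0]] = True
    touches_out[e[mixed][:, 1]] = True
    sources = np.where(pv & touches_out)[0]
    inner = pv[e[:, 0]] & pv[e[:, 1]]
    ee = e[inner]
    w = np.linalg.norm(mesh.vertices[ee[:, 0]] - mesh.vertices[ee[:, 1]], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.r_[w, w], (np.r_[ee[:, 0], ee[:, 1]], np.r_[ee[:, 1], ee[:, 0]])), shape=(n, n))
    dist = dijkstra(g.tocsr(), directed=False, indices=sources, min_only=True)
    return idx, dist


def pv_lengths(mesh: SurfaceMesh) -> dict[str, float]:
    """Geodesic length of each PV tube from its ostium curve to its rim."""
    out = {}
    for name in PV_LABELS:
        idx, dist = _pv_geodesics(mesh, LABELS[name])
        d = dist[idx]
        out[name] = float(d[np.isfinite(d)].max())
    return out


def clip_pulmonary_veins(mesh: SurfaceMesh, residual_length: float = 10.0) -> SurfaceMesh:
    """Truncate each PV so its geodesic length from the ostium is
    ``residual_length`` (default 10 mm), to within one edge length.

    A vein already shorter than ``residual_length`` is left intact with a
    warning.
    """
    if residual_length <= 0:
        raise GeometryError("residual_length must be > 0")
    keep = np.ones(mesh.n_vertices, dtype=bool)
    for name in PV_LABELS:
        idx, dist = _pv_geodesics(mesh, LABELS[name])
        d = dist[idx]
        finite = np.isfinite(d)
        if d[finite].max() <= residual_length:
            warnings.warn(f"{name} shorter than {residual_length} mm; left intact", stacklevel=2)
            continue
        keep[idx[finite & (d > residual_length + 1e-9)]] = False
        keep[idx[~finite]] = False
    clipped = mesh.submesh_from_vertex_mask(keep)
    clipped.check_manifold()
    return clipped
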