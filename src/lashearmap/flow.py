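"""Voxelized interior domain and a potential-flow surrogate.

The chamber interior is voxelized on a uniform grid (parity fill along
vertical columns of rays against the capped surface).  A discrete Laplace
problem with prescribed inlet/outlet fluxes yields a divergence-free face
velocity field; because the field is linear in the driving velocity, one
unit solve is scaled by the mitral waveform value at each time sample.  The
surrogate reproduces the volumetric exchange a transported scalar needs; it
is not a Navier-Stokes solution.

Units: geometry mm, face velocities mm/s (waveform m/s is converted at the
module boundary), time s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .mesh import LABELS, PV_LABELS, SurfaceMesh
from .waveform import VelocityWaveform


class FlowConfigurationError(ValueError):
    pass


@dataclass
class OrificeCap:
    """Planar cap closing one boundary loop: center, outward normal, radius."""

    label: str
    center: np.ndarray
    normal: np.ndarray
    radius: float


# face index convention: for axis a, face arrays have shape with +1 along a;
# face (i, j, k) on axis 0 separates cells (i-1, j, k) and (i, j, k).
@dataclass
class VoxelDomain:
    origin: np.ndarray  # corner of cell (0,0,0)
    spacing: float
    mask: np.ndarray  # (nx, ny, nz) bool, interior cells
    inlet_faces: dict = field(default_factory=dict)  # name -> (axis,i,j,k,sign) int array
    outlet_faces: np.ndarray | None = None
    caps: list = field(default_factory=list)
    # set by prescribe_flow:
    unit_face_u: list | None = None  # [ux, uy, uz] for unit outlet speed 1 mm/s
    sample_times: np.ndarray | None = None
    sample_scales: np.ndarray | None = None  # mm/s outlet speed per sample
    period: float | None = None

    @property
    def shape(self):
        return self.mask.shape

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())

    def cell_centers(self) -> np.ndarray:
        idx = np.argwhere(self.mask)
        return self.origin + (idx + 0.5) * self.spacing

    # ------------------------------------------------------------------
    def _face_shape(self, axis):
        s = list(self.mask.shape)
        s[axis] += 1
        return tuple(s)

    def boundary_faces(self) -> np.ndarray:
        """All mask-boundary faces as rows (axis, i, j, k, sign).

        sign = +1 if the exterior neighbor lies on the +axis side of the
        interior cell, so the outward normal is sign * e_axis.
        """
        rows = []
        m = self.mask
        for a in range(3):
            pad = [(0, 0)] * 3
            pad[a] = (1, 1)
            mp = np.pad(m, pad)
            lo = np.take(mp, range(0, m.shape[a] + 1), axis=a)
            hi = np.take(mp, range(1, m.shape[a] + 2), axis=a)
            # face f separates padded cells f-1 (lo) and f (hi)
            bnd = lo != hi
            idx = np.argwhere(bnd)
            sign = np.where(lo[tuple(idx.T)], 1, -1)  # interior below -> outward +
            rows.append(np.column_stack([np.full(len(idx), a), idx, sign]))
        return np.concatenate(rows).astype(np.int64)

    def face_centers(self, faces: np.ndarray) -> np.ndarray:
        c = (faces[:, 1:4] + 0.5) * self.spacing + self.origin
        for a in range(3):
            sel = faces[:, 0] == a
            c[sel, a] -= 0.5 * self.spacing
        return c

    # ------------------------------------------------------------------
    def cell_index_map(self):
        idmap = -np.ones(self.mask.shape, dtype=np.int64)
        idmap[self.mask] = np.arange(self.n_cells)
        return idmap

    def interior_faces(self):
        """Faces between two interior cells: (axis, i, j, k, cell_lo, cell_hi)."""
        idmap = self.cell_index_map()
        out = []
        for a in range(3):
            lo = np.take(self.mask, range(0, self.mask.shape[a] - 1), axis=a)
            hi = np.take(self.mask, range(1, self.mask.shape[a]), axis=a)
            both = lo & hi
            idx = np.argwhere(both)
            fidx = idx.copy()
            fidx[:, a] += 1  # face index between cell idx and idx+1 along a
            lo_cells = idmap[tuple(idx.T)]
            hi_idx = idx.copy()
            hi_idx[:, a] += 1
            hi_cells = idmap[tuple(hi_idx.T)]
            out.append(
                np.column_stack([np.full(len(idx), a), fidx, lo_cells, hi_cells])
            )
        return np.concatenate(out).astype(np.int64)

    # ------------------------------------------------------------------
    def face_velocity_arrays(self, scale: float = 1.0):
        """Face-normal velocity arrays [ux, uy, uz] at a given scale (mm/s)."""
        if self.unit_face_u is None:
            raise FlowConfigurationError("flow not prescribed; call prescribe_flow first")
        return [scale * u for u in self.unit_face_u]

    def cell_velocity(self, scale: float = 1.0) -> np.ndarray:
        """Cell-centered velocity (nx, ny, nz, 3) by face averaging."""
        ux, uy, uz = self.face_velocity_arrays(scale)
        out = np.zeros(self.mask.shape + (3,))
        out[..., 0] = 0.5 * (ux[:-1] + ux[1:])
        out[..., 1] = 0.5 * (uy[:, :-1] + uy[:, 1:])
        out[..., 2] = 0.5 * (uz[:, :, :-1] + uz[:, :, 1:])
        out[~self.mask] = 0.0
        return out

    def interpolate_unit_velocity(self, points: np.ndarray) -> np.ndarray:
        """Trilinear unit-scale velocity at arbitrary points (exterior cells
        filled with the nearest interior value before interpolation)."""
        u = self.cell_velocity(1.0)
        filled = np.empty_like(u)
        _, (ix, iy, iz) = ndimage.distance_transform_edt(~self.mask, return_indices=True)
        for c in range(3):
            filled[..., c] = u[ix, iy, iz, c]
        coords = (np.asarray(points) - self.origin) / self.spacing - 0.5
        out = np.empty((len(points), 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                filled[..., c], coords.T, order=1, mode="nearest"
            )
        return out

    def divergence(self, scale: float = 1.0) -> np.ndarray:
        """Net volumetric imbalance per interior cell, divided by cell volume,
        including the prescribed boundary fluxes (mm/s / mm = 1/s)."""
        ux, uy, uz = self.face_velocity_arrays(scale)
        h = self.spacing
        div = (
            (ux[1:] - ux[:-1]) + (uy[:, 1:] - uy[:, :-1]) + (uz[:, :, 1:] - uz[:, :, :-1])
        ) / h
        return div[self.mask]


# ----------------------------------------------------------------------
def cap_boundary_loops(mesh: SurfaceMesh):
    """Close every open boundary loop with a centroid fan.

    Returns the watertight mesh and one :class:`OrificeCap` per loop, with
    the loop's majority vertex label, plane center/normal (outward) and
    effective radius.
    """
    out = mesh.copy()
    caps = []
    centroid = out.vertices.mean(axis=0)
    loops = out.boundary_loops()
    verts = [out.vertices]
    faces = [out.triangles]
    labels = [out.vertex_labels]
    nv = out.n_vertices
    for loop in loops:
        pts = out.vertices[loop]
        c = pts.mean(axis=0)
        rel = pts - c
        _, _, vt = np.linalg.svd(rel)
        n = vt[2]
        if n @ (c - centroid) < 0:
            n = -n
        r = float(np.linalg.norm(rel, axis=1).mean())
        lab = int(np.bincount(out.vertex_labels[loop]).argmax())
        name = mesh.label_name(lab)
        caps.append(OrificeCap(label=name, center=c, normal=n, radius=r))
        verts.append(c[None, :])
        labels.append(np.array([lab], dtype=np.int64))
        ip1 = np.roll(np.arange(len(loop)), -1)
        # boundary directed edges are (loop[i], loop[i+1]); cap reverses them
        faces.append(np.column_stack([loop[ip1], loop, np.full(len(loop), nv)]))
        nv += 1
    capped = SurfaceMesh(
        vertices=np.concatenate(verts),
        triangles=np.concatenate(faces),
        vertex_labels=np.concatenate(labels),
    )
    return capped, caps


def _parity_fill(mesh: SurfaceMesh, origin, spacing, shape) -> np.ndarray:
    """Interior mask by vertical-ray crossing parity, one ray per (x, y)
    column.

    Candidate (triangle, column) pairs come from the triangles' xy bounding
    boxes; inside tests are 2D barycentric and the crossing height is read
    off the triangle plane.  Columns are jittered off the grid so rays do
    not graze vertices or edges.
    """
    nx, ny, nz = shape
    jit = np.array([1e-4 * spacing, 0.7e-4 * spacing])
    xs = origin[0] + (np.arange(nx) + 0.5) * spacing + jit[0]
    ys = origin[1] + (np.arange(ny) + 0.5) * spacing + jit[1]

    tri = mesh.vertices[mesh.triangles]  # (M, 3, 3)
    # column index spans of each triangle's xy bbox
    ix0 = np.clip(np.floor((tri[:, :, 0].min(axis=1) - xs[0]) / spacing), 0, nx - 1).astype(int)
    ix1 = np.clip(np.ceil((tri[:, :, 0].max(axis=1) - xs[0]) / spacing), 0, nx - 1).astype(int)
    iy0 = np.clip(np.floor((tri[:, :, 1].min(axis=1) - ys[0]) / spacing), 0, ny - 1).astype(int)
    iy1 = np.clip(np.ceil((tri[:, :, 1].max(axis=1) - ys[0]) / spacing), 0, ny - 1).astype(int)
    cx = ix1 - ix0 + 1
    cy = iy1 - iy0 + 1
    counts = cx * cy
    tri_id = np.repeat(np.arange(len(tri)), counts)
    # enumerate each triangle's (ix, iy) block
    offs = np.concatenate([np.arange(c) for c in counts]) if len(counts) else np.array([], int)
    ix = ix0[tri_id] + offs // cy[tri_id]
    iy = iy0[tri_id] + offs % cy[tri_id]

    px = xs[ix]
    py = ys[iy]
    a, b, c = tri[tri_id, 0], tri[tri_id, 1], tri[tri_id, 2]
    d = (b[:, 1] - c[:, 1]) * (a[:, 0] - c[:, 0]) + (c[:, 0] - b[:, 0]) * (a[:, 1] - c[:, 1])
    nzd = np.abs(d) > 1e-30
    with np.errstate(divide="ignore", invalid="ignore"):
        w1 = np.where(nzd, ((b[:, 1] - c[:, 1]) * (px - c[:, 0]) + (c[:, 0] - b[:, 0]) * (py - c[:, 1])) / d, -1)
        w2 = np.where(nzd, ((c[:, 1] - a[:, 1]) * (px - c[:, 0]) + (a[:, 0] - c[:, 0]) * (py - c[:, 1])) / d, -1)
    w3 = 1.0 - w1 - w2
    inside = (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
    zc_hit = w1 * a[:, 2] + w2 * b[:, 2] + w3 * c[:, 2]

    col = ix[inside] * ny + iy[inside]
    zhit = zc_hit[inside]
    order = np.lexsort((zhit, col))
    col, zhit = col[order], zhit[order]

    mask = np.zeros(shape, dtype=bool)
    zcells = origin[2] + (np.arange(nz) + 0.5) * spacing
    starts = np.searchsorted(col, np.arange(nx * ny))
    ends = np.searchsorted(col, np.arange(nx * ny), side="right")
    for cidx in np.unique(col):
        zs = zhit[starts[cidx] : ends[cidx]]
        if len(zs) < 2:
            continue
        if len(zs) % 2 == 1:  # tangential graze
            zs = zs[:-1]
        i, j = divmod(int(cidx), ny)
        inside_z = np.zeros(nz, dtype=bool)
        for lo_z, hi_z in zip(zs[0::2], zs[1::2]):
            inside_z |= (zcells > lo_z) & (zcells < hi_z)
        mask[i, j] = inside_z
    return mask


def voxelize(mesh: SurfaceMesh, spacing: float) -> VoxelDomain:
    """Voxelize the chamber interior and label inlet/outlet boundary faces.

    Open boundary loops are capped first; caps with PV labels become inlets,
    the mitral cap the outlet.  Raises if the spacing cannot resolve a PV
    tube (diameter < 3 voxels).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    capped, caps = cap_boundary_loops(mesh) if mesh.boundary_loops() else (mesh, [])
    for cap in caps:
        if cap.label in PV_LABELS and 2 * cap.radius < 3 * spacing:
            raise FlowConfigurationError(
                f"spacing {spacing} mm too coarse for {cap.label} "
                f"(diameter {2 * cap.radius:.1f} mm < 3 voxels)"
            )
    lo = capped.vertices.min(axis=0) - spacing
    hi = capped.vertices.max(axis=0) + spacing
    shape = tuple(np.ceil((hi - lo) / spacing).astype(int))
    origin = lo
    mask = _parity_fill(capped, origin, spacing, shape)
    # largest connected component only
    lab, n = ndimage.label(mask)
    if n == 0:
        raise FlowConfigurationError("voxelization produced an empty interior")
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=range(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))

    dom = VoxelDomain(origin=np.asarray(origin, float), spacing=spacing, mask=mask, caps=caps)
    bf = dom.boundary_faces()
    fc = dom.face_centers(bf)
    assigned = np.zeros(len(bf), dtype=bool)
    inlets = {}
    outlet = None
    axes = np.eye(3)
    for cap in caps:
        for tol in (0.9, 1.5):
            plane_d = np.abs((fc - cap.center) @ cap.normal)
            inplane = np.linalg.norm(
                (fc - cap.center) - np.outer((fc - cap.center) @ cap.normal, cap.normal),
                axis=1,
            )
            outward = (axes[bf[:, 0]] * bf[:, 4][:, None] * cap.normal).sum(axis=1)
            sel = (
                (plane_d <= tol * spacing)
                & (inplane <= cap.radius + spacing)
                & (outward > 0.3)
                & ~assigned
            )
            if sel.any():
                break
        if not sel.any():
            raise FlowConfigurationError(f"no boundary faces found for orifice {cap.label}")
        assigned |= sel
        if cap.label == "mitral_rim":
            outlet = bf[sel]
        else:
            inlets[cap.label] = bf[sel]
    dom.inlet_faces = inlets
    dom.outlet_faces = outlet
    return dom


def box_domain(
    n_cells: tuple[int, int, int],
    spacing: float = 1.0,
    inlet_axis: int | None = 0,
    outlet_axis: int | None = 0,
    two_sided_dirichlet: bool = False,
) -> VoxelDomain:
    """Axis-aligned all-interior box, with optional full-face inlet/outlet on
    the low/high ends of an axis.  Convenience for solver verification."""
    mask = np.ones(n_cells, dtype=bool)
    dom = VoxelDomain(origin=np.zeros(3), spacing=spacing, mask=mask)
    bf = dom.boundary_faces()

    def face_set(axis, side):
        if side == "low":
            return bf[(bf[:, 0] == axis) & (bf[:, 1 + axis] == 0)]
        return bf[(bf[:, 0] == axis) & (bf[:, 1 + axis] == n_cells[axis])]

    inlets = {}
    outlet = None
    if inlet_axis is not None:
        inlets["LSPV"] = face_set(inlet_axis, "low")
    if two_sided_dirichlet:
        inlets["RSPV"] = face_set(inlet_axis, "high")
    elif outlet_axis is not None:
        outlet = face_set(outlet_axis, "high")
    dom.inlet_faces = inlets
    dom.outlet_faces = outlet
    return dom


def _scatter_faces(dom, arrays, faces, values):
    """Write face-normal velocity components for boundary faces.

    ``values`` is the signed axis component (+ along +axis)."""
    for a in range(3):
        sel = faces[:, 0] == a
        if sel.any():
            arrays[a][tuple(faces[sel, 1:4].T)] = values[sel] if np.ndim(values) else values


def prescribe_flow(
    domain: VoxelDomain,
    waveform: VelocityWaveform,
    split=None,
) -> VoxelDomain:
    """Solve the unit potential-flow problem and attach the waveform schedule.

    The outlet face speed is the waveform velocity; each inlet carries a
    fixed fraction of the total volumetric flux (default: equal split).  The
    interior field solves a discrete Laplace problem, so every interior cell
    is divergence-free to solver precision and total inlet flux equals total
    outlet flux by construction at every time sample.
    """
    if domain.outlet_faces is None or len(domain.outlet_faces) == 0:
        raise FlowConfigurationError("domain has no outlet; potential problem is singular")
    names = sorted(domain.inlet_faces)
    if not names:
        raise FlowConfigurationError("domain has no inlets")
    if split is None:
        split = {n: 1.0 / len(names) for n in names}
    total = sum(split[n] for n in names)
    if abs(total - 1.0) > 1e-9:
        raise FlowConfigurationError(f"inlet split sums to {total}, expected 1")

    h = domain.spacing
    n = domain.n_cells
    idmap = domain.cell_index_map()
    ifaces = domain.interior_faces()
    lo, hi = ifaces[:, 4], ifaces[:, 5]
    # graph Laplacian: (phi_c - phi_nb) * h summed over faces = RHS flux / h^2 * h
    rows = np.r_[lo, hi, lo, hi]
    cols = np.r_[lo, hi, hi, lo]
    vals = np.r_[np.ones(len(lo)), np.ones(len(lo)), -np.ones(len(lo)), -np.ones(len(lo))]
    A = coo_matrix((vals * h, (rows, cols)), shape=(n, n)).tocsr()

    b = np.zeros(n)
    out_faces = domain.outlet_faces
    q_out_total = len(out_faces) * h * h * 1.0  # unit outlet speed 1 mm/s
    inlet_speeds = {}
    for name in names:
        f = domain.inlet_faces[name]
        q = split[name] * q_out_total
        u_in = q / (len(f) * h * h)
        inlet_speeds[name] = u_in
        cells = _adjacent_cells(domain, f, idmap)
        np.add.at(b, cells, u_in * h * h)
    cells_out = _adjacent_cells(domain, out_faces, idmap)
    np.add.at(b, cells_out, -1.0 * h * h)

    # ground one cell (solution defined up to a constant)
    A = A.tolil()
    A[0, :] = 0.0
    A[0, 0] = 1.0
    b[0] = 0.0
    phi = spsolve(A.tocsr(), b)

    ux = np.zeros(domain._face_shape(0))
    uy = np.zeros(domain._face_shape(1))
    uz = np.zeros(domain._face_shape(2))
    arrays = [ux, uy, uz]
    for a in range(3):
        sel = ifaces[:, 0] == a
        f = ifaces[sel]
        arrays[a][tuple(f[:, 1:4].T)] = -(phi[f[:, 5]] - phi[f[:, 4]]) / h
    for name in names:
        f = domain.inlet_faces[name]
        # inflow: velocity points opposite the outward sign
        _scatter_faces(domain, arrays, f, -f[:, 4].astype(float) * inlet_speeds[name])
    _scatter_faces(domain, arrays, out_faces, out_faces[:, 4].astype(float) * 1.0)

    domain.unit_face_u = arrays
    domain.sample_times = waveform.times.copy()
    domain.sample_scales = waveform.velocity * 1e3  # m/s -> mm/s
    domain.period = waveform.period
    return domain


def _adjacent_cells(domain, faces, idmap):
    """Interior cell adjacent to each boundary face."""
    cell_idx = faces[:, 1:4].copy()
    for a in range(3):
        sel = (faces[:, 0] == a) & (faces[:, 4] == 1)
        cell_idx[sel, a] -= 1
    # for sign=-1 the interior cell is at the face index itself
    return idmap[tuple(cell_idx.T)]


def flux_balance(domain: VoxelDomain, scale: float = 1.0):
    """(total inlet flux, total outlet flux) in mm^3/s at a given scale."""
    arrays = domain.face_velocity_arrays(scale)
    h2 = domain.spacing**2

    def face_flux(faces):
        vals = np.empty(len(faces))
        for a in range(3):
            sel = faces[:, 0] == a
            vals[sel] = arrays[a][tuple(faces[sel, 1:4].T)]
        # signed outward flux
        return float((vals * faces[:, 4]).sum() * h2)

    q_in = -sum(face_flux(f) for f in domain.inlet_faces.values())
    q_out = face_flux(domain.outlet_faces) if domain.outlet_faces is not None else 0.0
    return q_in, q_out
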