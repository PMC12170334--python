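"""Blood-age transport: da/dt + u . grad(a) = D lap(a) + 1.

Blood age is the mean time blood has spent inside the chamber, computed as a
passive scalar with a unit volumetric source: fresh blood enters the
pulmonary veins with age zero, ages one second per second everywhere, and
leaves through the mitral orifice.  High steady-cycle age marks stagnation.

Discretization: finite volume on the voxel grid, first-order upwind
advection, central diffusion with Dirichlet age 0 at inlet faces (half-cell
ghost) and zero-gradient at the outlet, implicit backward Euler in time
(unconditionally stable, so the fixed small time step is a fidelity choice,
not a stability constraint).  The face velocities are the unit potential
field scaled by the waveform, so the advection operator at any time sample
is a scalar multiple of one precomputed matrix and the factorizations are
cached per distinct scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, identity
from scipy.sparse.linalg import factorized

from .fields import ScalarField
from .flow import VoxelDomain
from .mesh import SurfaceMesh


@dataclass
class AgeField:
    """Blood age (s) per voxel; NaN outside the interior mask."""

    values: np.ndarray  # (nx, ny, nz)
    elapsed: float
    cycles: int
    domain: VoxelDomain
    meta: dict = field(default_factory=dict)

    def interior_values(self) -> np.ndarray:
        return self.values[self.domain.mask]


def _face_cell_tables(domain: VoxelDomain):
    idmap = domain.cell_index_map()
    ifaces = domain.interior_faces()
    bfaces = domain.boundary_faces()
    from .flow import _adjacent_cells

    bcells = _adjacent_cells(domain, bfaces, idmap)
    inlet_rows = set()
    for f in domain.inlet_faces.values():
        inlet_rows.update(map(tuple, f[:, :5]))
    outlet_rows = (
        set(map(tuple, domain.outlet_faces[:, :5]))
        if domain.outlet_faces is not None
        else set()
    )
    kinds = np.array(
        [
            "inlet" if tuple(r[:5]) in inlet_rows else
            "outlet" if tuple(r[:5]) in outlet_rows else "wall"
            for r in bfaces
        ]
    )
    return idmap, ifaces, bfaces, bcells, kinds


def _advection_matrix(domain, ifaces, bfaces, bcells, kinds, sign: float):
    """Upwind advection operator A such that (A a)_c = (1/V) sum outflux a_up,
    for the unit face field multiplied by ``sign`` (supports reversed flow)."""
    h = domain.spacing
    n = domain.n_cells
    u = domain.unit_face_u
    rows, cols, vals = [], [], []
    # interior faces: flux from lo to hi is +u * h^2
    for a in range(3):
        f = ifaces[ifaces[:, 0] == a]
        uf = sign * u[a][tuple(f[:, 1:4].T)]
        lo, hi = f[:, 4], f[:, 5]
        up = np.where(uf > 0, lo, hi)
        flux = np.abs(uf) * h * h / h**3  # |flux| / V = |u| / h
        dn = np.where(uf > 0, hi, lo)
        # upwind donor loses, receiver gains
        rows += [up, dn]
        cols += [up, up]
        vals += [flux, -flux]
    # boundary faces: outflow contributes a diagonal sink; inflow carries age 0
    for a in range(3):
        sel = bfaces[:, 0] == a
        f = bfaces[sel]
        cells = bcells[sel]
        k = kinds[sel]
        uf = sign * u[a][tuple(f[:, 1:4].T)]
        outflux = uf * f[:, 4]  # positive = leaving the domain
        leaving = (outflux > 0) & (k != "wall")
        flux = outflux[leaving] / h
        rows.append(cells[leaving])
        cols.append(cells[leaving])
        vals.append(flux)
    rows = np.concatenate([np.atleast_1d(r) for r in rows])
    cols = np.concatenate([np.atleast_1d(c) for c in cols])
    vals = np.concatenate([np.atleast_1d(v) for v in vals])
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _diffusion_matrix(domain, ifaces, bfaces, bcells, kinds, diffusivity: float):
    """Central diffusion with Dirichlet a=0 at inlets (half-cell), natural
    elsewhere; returns L such that (L a)_c = D lap(a)_c."""
    h = domain.spacing
    n = domain.n_cells
    d = diffusivity / h**2
    lo, hi = ifaces[:, 4], ifaces[:, 5]
    rows = np.r_[lo, hi, lo, hi]
    cols = np.r_[hi, lo, lo, hi]
    vals = np.r_[np.full(len(lo), d), np.full(len(lo), d), np.full(len(lo), -d), np.full(len(lo), -d)]
    L = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    is_inlet = kinds == "inlet"
    if is_inlet.any():
        cells = bcells[is_inlet]
        Lb = coo_matrix(
            (np.full(len(cells), -2.0 * d), (cells, cells)), shape=(n, n)
        ).tocsr()
        L = L + Lb
    return L


def solve_blood_age(
    domain: VoxelDomain,
    n_cycles: int = 6,
    dt: float = 2.5e-4,
    diffusivity: float = 1.0,
    period: float | None = None,
) -> AgeField:
    """Integrate the age equation over ``n_cycles`` heart periods.

    ``diffusivity`` is in mm^2/s (the physical value for blood age is not
    well constrained; the default 1.0 mm^2/s is a numerically gentle choice
    and is recorded in the result metadata).  A domain without prescribed
    flow is integrated as pure source + diffusion with ``period`` (s).
    """
    if n_cycles < 1 or dt <= 0:
        raise ValueError("n_cycles >= 1 and dt > 0 required")
    idmap, ifaces, bfaces, bcells, kinds = _face_cell_tables(domain)
    n = domain.n_cells
    L = _diffusion_matrix(domain, ifaces, bfaces, bcells, kinds, diffusivity)

    if domain.unit_face_u is not None and domain.sample_times is not None:
        times = domain.sample_times
        scales = domain.sample_scales
        T = domain.period
        A_pos = _advection_matrix(domain, ifaces, bfaces, bcells, kinds, 1.0)
        A_neg = _advection_matrix(domain, ifaces, bfaces, bcells, kinds, -1.0)
    else:
        if period is None:
            period = 1.0
        times = np.array([0.0])
        scales = np.array([0.0])
        T = period
        A_pos = A_neg = coo_matrix((n, n)).tocsr()

    I = identity(n, format="csr")
    a = np.zeros(n)
    solvers: dict[tuple, object] = {}
    edges = np.append(times, T)
    for _ in range(n_cycles):
        for k in range(len(times)):
            span = edges[k + 1] - edges[k]
            n_sub = max(1, int(np.ceil(span / dt)))
            dt_sub = span / n_sub
            s = float(scales[k])
            key = (round(s, 12), round(dt_sub, 15))
            if key not in solvers:
                A = A_pos if s >= 0 else A_neg
                M = I + dt_sub * (abs(s) * A - L)
                solvers[key] = factorized(M.tocsc())
            solve = solvers[key]
            for _ in range(n_sub):
                a = solve(a + dt_sub)
    elapsed = n_cycles * T
    vals = np.full(domain.mask.shape, np.nan)
    vals[domain.mask] = a
    return AgeField(
        values=vals,
        elapsed=elapsed,
        cycles=n_cycles,
        domain=domain,
        meta={"dt": dt, "diffusivity": diffusivity, "n_factorizations": len(solvers)},
    )


def sample_near_wall(
    age: AgeField, mesh: SurfaceMesh, offset: float = 1.0
) -> ScalarField:
    """Sample blood age ``offset`` mm inside the wall at every vertex.

    The probe point is vertex - offset * outward normal; values are
    trilinearly interpolated from the voxel field (exterior voxels filled
    with their nearest interior value first).  Probes that land outside the
    interior fall back to the nearest interior voxel; the count is reported
    in the field metadata.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    dom = age.domain
    normals = mesh.vertex_normals()
    probes = mesh.vertices - offset * normals

    filled = age.values.copy()
    _, (ix, iy, iz) = ndimage.distance_transform_edt(~dom.mask, return_indices=True)
    filled = filled[ix, iy, iz]

    coords = (probes - dom.origin) / dom.spacing - 0.5
    vals = ndimage.map_coordinates(filled, coords.T, order=1, mode="nearest")

    nearest = np.clip(
        np.round(coords).astype(int), 0, np.array(dom.mask.shape) - 1
    )
    inside = dom.mask[tuple(nearest.T)]
    fallback = int((~inside).sum())
    return ScalarField(
        vals, name="BA", units="s", meta={"offset_mm": offset, "fallback_count": fallback}
    )
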