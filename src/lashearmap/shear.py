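"""Wall-shear indices from a traction time series.

Given the tangential traction vector tau(t) over one heart period T, the
standard indices are

* TAWSS   = (1/T) integral ||tau|| dt                      (Pa)
* OSI     = 0.5 (1 - ||(1/T) integral tau dt|| / TAWSS)    (-)
* ECAP    = OSI / TAWSS                                    (1/Pa)
* RRT     = 1 / ||(1/T) integral tau dt||                  (1/Pa)
* HOLMES  = TAWSS (0.5 - OSI)                              (Pa)
* WSSG    = (1/T) integral grad||tau|| . tau/||tau|| dt    (Pa/mm)

All integrals use periodic trapezoidal quadrature with the first sample
reused to close the period.  OSI is 0 for steady traction and 0.5 for a
fully reversing one.  Where the time-averaged traction vector vanishes, RRT
and ECAP are reported as +inf with a defined-mask so downstream statistics
exclude rather than cap them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import ScalarField
from .mesh import SurfaceMesh
from .traction import TractionSeries


@dataclass
class ShearIndexSet:
    tawss: ScalarField
    osi: ScalarField
    ecap: ScalarField
    rrt: ScalarField
    holmes: ScalarField
    flow_direction: np.ndarray  # unit mean-traction direction, (N, 3)
    defined: np.ndarray  # mask where RRT/ECAP are finite
    wssg: ScalarField | None = None
    meta: dict = field(default_factory=dict)

    def as_table(self) -> dict[str, np.ndarray]:
        cols = {
            "TAWSS": self.tawss.values,
            "OSI": self.osi.values,
            "ECAP": self.ecap.values,
            "RRT": self.rrt.values,
            "HOLMES": self.holmes.values,
        }
        if self.wssg is not None:
            cols["WSSG"] = self.wssg.values
        return cols


def _periodic_closure(series: TractionSeries):
    t = np.append(series.times, series.times[0] + series.period)
    tau = np.concatenate([series.tau, series.tau[:1]], axis=0)
    return t, tau


def compute_shear_indices(series: TractionSeries) -> ShearIndexSet:
    """TAWSS, OSI, ECAP, RRT, HOLMES and the mean flow direction."""
    t, tau = _periodic_closure(series)
    T = series.period
    mag = np.linalg.norm(tau, axis=2)
    tawss = np.trapezoid(mag, t, axis=0) / T
    mean_vec = np.trapezoid(tau, t, axis=0) / T
    mean_mag = np.linalg.norm(mean_vec, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        osi = 0.5 * (1.0 - mean_mag / tawss)
    osi = np.clip(np.where(tawss > 0, osi, 0.0), 0.0, 0.5)

    defined = mean_mag > 0
    ecap = np.full_like(tawss, np.inf)
    rrt = np.full_like(tawss, np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(osi, tawss, out=ecap, where=tawss > 0)
        np.divide(1.0, mean_mag, out=rrt, where=defined)
    ecap = np.where(defined, ecap, np.inf)
    holmes = tawss * (0.5 - osi)

    g = np.zeros_like(mean_vec)
    np.divide(mean_vec, mean_mag[:, None], out=g, where=defined[:, None])

    return ShearIndexSet(
        tawss=ScalarField(tawss, "TAWSS", "Pa"),
        osi=ScalarField(osi, "OSI", ""),
        ecap=ScalarField(ecap, "ECAP", "1/Pa"),
        rrt=ScalarField(rrt, "RRT", "1/Pa"),
        holmes=ScalarField(holmes, "HOLMES", "Pa"),
        flow_direction=g,
        defined=defined,
        meta={"n_samples": series.n_samples, "period": series.period},
    )


def surface_scalar_gradient(mesh: SurfaceMesh, values) -> np.ndarray:
    """Per-vertex tangential gradient of a vertex scalar field.

    Linear shape functions give an exact per-face gradient
    grad f = (1 / 2A) sum_i f_i (n x e_i), with e_i the edge opposite
    vertex i; face gradients are averaged onto vertices with area weights.
    Degenerate (zero-area) faces are skipped.
    """
    f = np.asarray(getattr(values, "values", values), dtype=float)
    if len(f) != mesh.n_vertices:
        raise ValueError("field must be defined on all vertices")
    tri = mesh.triangles
    p = mesh.vertices[tri]
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    n = np.cross(e2, -e1)  # 2A * unit normal
    two_a = np.linalg.norm(n, axis=1)
    ok = two_a > 1e-14
    nhat = np.zeros_like(n)
    nhat[ok] = n[ok] / two_a[ok, None]
    fv = f[tri]
    grad_face = (
        fv[:, 0, None] * np.cross(nhat, e0)
        + fv[:, 1, None] * np.cross(nhat, e1)
        + fv[:, 2, None] * np.cross(nhat, e2)
    )
    grad_face[ok] /= two_a[ok, None]
    grad_face[~ok] = 0.0

    areas = 0.5 * two_a
    acc = np.zeros((mesh.n_vertices, 3))
    wsum = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(acc, tri[:, k], grad_face * areas[:, None])
        np.add.at(wsum, tri[:, k], areas)
    wsum[wsum == 0] = 1.0
    return acc / wsum[:, None]


def compute_wssg(
    series: TractionSeries, mesh: SurfaceMesh, mode: str = "instantaneous"
) -> ScalarField:
    """Time-averaged wall shear stress gradient along the flow direction.

    Per time sample the surface gradient of ||tau|| is projected onto the
    unit traction direction; the projections are averaged over the period.
    ``mode="mean-direction"`` projects onto the time-averaged traction
    direction instead (both readings of the ambiguous operator are offered).
    Samples with zero traction magnitude contribute 0 at that vertex and are
    counted in the returned metadata.
    """
    if mode not in ("instantaneous", "mean-direction"):
        raise ValueError("mode must be 'instantaneous' or 'mean-direction'")
    if series.n_vertices != mesh.n_vertices:
        raise ValueError("series and mesh vertex counts differ")
    t, tau = _periodic_closure(series)
    T = series.period
    mag = np.linalg.norm(tau, axis=2)

    if mode == "mean-direction":
        g_dir = compute_shear_indices(series).flow_direction

    proj = np.zeros_like(mag)
    zero_count = 0
    for k in range(tau.shape[0]):
        grad = surface_scalar_gradient(mesh, mag[k])
        if mode == "instantaneous":
            dirk = np.zeros_like(tau[k])
            nz = mag[k] > 0
            zero_count += int((~nz).sum())
            dirk[nz] = tau[k][nz] / mag[k][nz, None]
        else:
            dirk = g_dir
        proj[k] = np.einsum("ij,ij->i", grad, dirk)
    wssg = np.trapezoid(proj, t, axis=0) / T
    return ScalarField(wssg, "WSSG", "Pa/mm", meta={"mode": mode, "zero_traction_samples": zero_count})
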