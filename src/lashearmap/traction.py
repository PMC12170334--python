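"""Per-vertex wall-traction (wall shear stress vector) time series.

The shear indices only need the tangential traction sampled over one heart
period.  Two sources are provided: a synthetic generator with prescribed
time-average and oscillation (so the downstream indices have known ground
truth), and a near-wall finite-difference surrogate that reads the tangential
velocity of the voxel flow field one offset inside the wall.  The surrogate
is a first-order estimate of viscous traction, not a Navier-Stokes solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import ScalarField
from .mesh import SurfaceMesh


@dataclass
class TractionSeries:
    """Traction vectors tau (Pa) per vertex over one period.

    ``times`` (s) span exactly one period [0, T); ``tau`` has shape
    (n_samples, n_vertices, 3).
    """

    times: np.ndarray
    tau: np.ndarray
    period: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.tau.ndim != 3 or self.tau.shape[2] != 3:
            raise ValueError("tau must have shape (n_samples, n_vertices, 3)")
        if len(self.times) != self.tau.shape[0]:
            raise ValueError("times length must match tau samples")
        if len(self.times) < 8:
            raise ValueError("need at least 8 time samples over the period")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0 or self.times[-1] >= self.period:
            raise ValueError("times must span [0, T)")
        if not np.all(np.isfinite(self.tau)):
            raise ValueError("traction vectors must be finite")

    @property
    def n_samples(self) -> int:
        return self.tau.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.tau.shape[1]


def _tangent_basis(normals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.tile(np.array([1.0, 0.0, 0.0]), (len(normals), 1))
    a[np.abs(normals[:, 0]) > 0.9] = [0.0, 1.0, 0.0]
    e1 = np.cross(normals, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(normals, e1)
    return e1, e2


def synthesize_traction_series(
    mesh: SurfaceMesh,
    mean_magnitude: ScalarField,
    oscillation,
    n_samples: int = 32,
    seed: int = 0,
) -> TractionSeries:
    """Tangential traction series with prescribed TAWSS and oscillation.

    Per vertex the traction is a square-wave sign pattern along a random
    tangent direction: magnitude fixed at ``mean_magnitude`` (so TAWSS equals
    it exactly under any periodic quadrature) and sign positive for a
    fraction ``1 - oscillation/2`` of the period, which yields
    OSI = oscillation / 2 up to the 1/n_samples discretization.
    ``oscillation`` in [0, 1]: 0 steady, 1 fully reversing.
    """
    osc = np.broadcast_to(np.asarray(oscillation, dtype=float), (mesh.n_vertices,)).copy()
    if (osc < 0).any() or (osc > 1).any():
        raise ValueError("oscillation must lie in [0, 1]")
    mag = np.asarray(mean_magnitude.values, dtype=float)
    if len(mag) != mesh.n_vertices:
        raise ValueError("mean_magnitude must be a per-vertex field")
    rng = np.random.default_rng(seed)
    normals = mesh.vertex_normals()
    e1, e2 = _tangent_basis(normals)
    phi = rng.uniform(0, 2 * np.pi, mesh.n_vertices)
    direction = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2

    period = 1.0
    times = np.arange(n_samples) * (period / n_samples)
    # positive fraction f = 1 - osi = 1 - osc/2
    n_pos = np.round((1.0 - osc / 2.0) * n_samples).astype(int)
    sign = np.where(np.arange(n_samples)[:, None] < n_pos[None, :], 1.0, -1.0)
    tau = sign[:, :, None] * (mag[None, :, None] * direction[None, :, :])
    return TractionSeries(times=times, tau=tau, period=period)


def estimate_wall_traction(
    domain,
    mesh: SurfaceMesh,
    viscosity: float = 3.5e-3,
    offset: float = 1.0,
) -> TractionSeries:
    """Near-wall finite-difference traction surrogate.

    tau ~= mu * u_t(offset) / offset, with u_t the tangential velocity
    interpolated ``offset`` mm inside the wall.  mu in Pa.s, velocities are
    converted from mm/s to m/s so tau is in Pa.  First-order surrogate for
    the viscous wall traction; documented as such, not a CFD traction.
    """
    if offset < domain.spacing:
        raise ValueError("offset must be at least one voxel spacing")
    normals = mesh.vertex_normals()
    probe = mesh.vertices - offset * normals
    u_unit = domain.interpolate_unit_velocity(probe)  # (N, 3), mm/s per unit scale
    u_tan = u_unit - np.einsum("ij,ij->i", u_unit, normals)[:, None] * normals
    base = viscosity * (u_tan * 1e-3) / (offset * 1e-3)  # Pa at unit scale
    scales = domain.sample_scales
    times = domain.sample_times
    tau = scales[:, None, None] * base[None, :, :]
    return TractionSeries(times=times, tau=tau, period=domain.period)
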