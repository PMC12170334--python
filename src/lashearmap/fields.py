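"""Per-vertex scalar fields and synthetic clinical-data fixtures.

Bipolar voltage (BV, mV) and the image intensity ratio (IIR, dimensionless)
are generated with a Gaussian-copula construction against a given TAWSS
field, so the prescribed Pearson correlation structure (negative for BV,
positive for IIR, as observed clinically) is known exactly by design and can
be recovered by the statistics stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .mesh import SurfaceMesh


@dataclass
class ScalarField:
    """One real value per mesh vertex; NaN marks missing."""

    values: np.ndarray
    name: str = ""
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self):
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def _smooth_noise(points: np.ndarray, rng, correlation_length: float, n_waves: int = 64):
    """Zero-mean smooth random field: random Fourier features with wave
    numbers around 2 pi / correlation_length (mm)."""
    k = rng.standard_normal((n_waves, 3))
    k /= np.linalg.norm(k, axis=1, keepdims=True)
    k *= (2 * np.pi / correlation_length) * (0.5 + rng.random((n_waves, 1)))
    phase = rng.uniform(0, 2 * np.pi, n_waves)
    amp = rng.standard_normal(n_waves)
    f = (amp[None, :] * np.cos(points @ k.T + phase[None, :])).sum(axis=1)
    return f


def synthesize_wall_fields(
    mesh: SurfaceMesh,
    tawss: ScalarField,
    rho_bv: float = -0.4,
    rho_iir: float = 0.3,
    bv_range: tuple[float, float] = (0.1, 5.0),
    iir_range: tuple[float, float] = (0.8, 1.6),
    noise_length: float = 8.0,
    seed: int = 0,
) -> tuple[ScalarField, ScalarField]:
    """Synthesize BV and IIR fields rank-correlated with TAWSS.

    Construction: standardized TAWSS values are mixed with a spatially
    smooth Gaussian noise field (correlation length ``noise_length`` mm;
    clinical BV and IIR maps vary over millimetres, not per vertex) and the
    mix is pushed through its empirical CDF onto the requested range, so
    the output marginal is exactly uniform on the range.  The mixing weight
    is calibrated by root finding so the empirical Pearson correlation
    between the TAWSS ranks and the output equals the prescribed rho for
    this realization (root bracketed to ~1/N; exact monotone map in the
    ``rho = +/-1`` limits).  Using the TAWSS values rather than their ranks
    in the mix keeps the output spatially smooth even where the TAWSS
    marginal concentrates, which is what lets the field survive
    catheter-style resampling and interpolation.
    """
    from scipy.optimize import brentq

    for rho in (rho_bv, rho_iir):
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"correlation {rho} outside [-1, 1]")
    if len(tawss) != mesh.n_vertices:
        raise ValueError("tawss must be defined on the mesh vertices")
    if bv_range[0] >= bv_range[1] or iir_range[0] >= iir_range[1]:
        raise ValueError("ranges must be ordered (low, high)")
    rng = np.random.default_rng(seed)
    x = np.asarray(tawss.values, dtype=float)
    z = (x - x.mean()) / x.std()
    rank_x = rankdata(x, method="average")
    n = len(x)

    def uniformize(v):
        return (rankdata(v, method="average") - 0.5) / n

    u_x = uniformize(x)
    out = []
    for rho, (lo, hi), name, units in (
        (rho_bv, bv_range, "BV", "mV"),
        (rho_iir, iir_range, "IIR", ""),
    ):
        eps = _smooth_noise(mesh.vertices, rng, noise_length)
        eps = (eps - eps.mean()) / eps.std()

        def achieved(w):
            mix = w * z + np.sqrt(max(0.0, 1.0 - w * w)) * eps
            r = np.corrcoef(u_x, uniformize(mix))[0, 1]
            return r - rho

        if abs(rho) >= 1.0 - 1e-12:
            mix = np.sign(rho) * rank_x
        else:
            lo_w, hi_w = -1.0 + 1e-12, 1.0 - 1e-12
            if achieved(lo_w) > 0:
                w = lo_w
            elif achieved(hi_w) < 0:
                w = hi_w
            else:
                w = brentq(achieved, lo_w, hi_w, xtol=1e-6)
            mix = w * z + np.sqrt(max(0.0, 1.0 - w * w)) * eps
        vals = lo + (hi - lo) * uniformize(mix)
        out.append(
            ScalarField(vals, name=name, units=units, meta={"rho_target": rho, "seed": seed})
        )
    return out[0], out[1]


@dataclass
class EmapCloud:
    """Synthetic electroanatomical point cloud with ground truth attached.

    ``points`` are in the displaced (acquisition) frame; ``true_transform``
    maps them back onto the source mesh frame and is stored so registration
    tests can assert exact recovery.
    """

    points: np.ndarray
    bv: np.ndarray
    true_transform: "object"  # RigidTransform; avoids an import cycle
    source_points: np.ndarray = None


def sample_surface_points(mesh: SurfaceMesh, n_points: int, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Area-weighted uniform sampling; returns points, face ids, barycentric."""
    areas = mesh.triangle_areas()
    faces = rng.choice(len(areas), size=n_points, p=areas / areas.sum())
    r1, r2 = rng.random(n_points), rng.random(n_points)
    s = np.sqrt(r1)
    bary = np.column_stack([1 - s, s * (1 - r2), s * r2])
    tri = mesh.vertices[mesh.triangles[faces]]
    pts = np.einsum("ij,ijk->ik", bary, tri)
    return pts, faces, bary


def synthesize_emap_cloud(
    mesh: SurfaceMesh,
    n_points: int,
    transform=None,
    jitter_sd: float = 0.5,
    bv_field: ScalarField | None = None,
    seed: int = 0,
) -> EmapCloud:
    """Sample an electroanatomical cloud from the mesh surface.

    Points are drawn uniformly by area, carry the barycentrically
    interpolated BV value, are jittered isotropically (catheter positional
    noise) and finally moved by ``transform`` (the unknown pose an ICP stage
    must recover).
    """
    from .mapping import RigidTransform

    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    if transform is None:
        transform = RigidTransform.identity()
    rng = np.random.default_rng(seed)
    pts, faces, bary = sample_surface_points(mesh, n_points, rng)
    if bv_field is not None:
        vals = bv_field.values[mesh.triangles[faces]]
        bv = np.einsum("ij,ij->i", bary, vals)
    else:
        bv = np.zeros(n_points)
    source = pts.copy()
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    moved = transform.apply(pts)
    return EmapCloud(points=moved, bv=bv, true_transform=transform, source_points=source)
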