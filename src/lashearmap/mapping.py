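"""Rigid registration and scattered field transfer.

Electroanatomical point clouds and imaging-derived surfaces live in their
own acquisition frames; they are aligned to the hemodynamic mesh with
point-to-point iterative closest point (nearest-neighbor correspondence and
an SVD rigid fit per iteration) and their scalar values are transferred by
3D radial basis function interpolation with an affine polynomial term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .fields import ScalarField
from .mesh import SurfaceMesh

_KERNELS = {
    "thin-plate": "thin_plate_spline",
    "linear": "linear",
    "gaussian": "gaussian",
}


class RegistrationError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has det -1 (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0, 0, 0)) -> "RigidTransform":
        axis = np.asarray(axis, float)
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def kabsch(source: np.ndarray, target: np.ndarray, scale: bool = False):
    """Least-squares similarity/rigid fit of paired point sets (SVD).

    Returns (R, t, s) minimizing ||s R x + t - y||^2 with s = 1 when
    ``scale`` is False (Umeyama's method with the reflection guard).
    """
    src_c = source.mean(axis=0)
    tgt_c = target.mean(axis=0)
    X = source - src_c
    Y = target - tgt_c
    H = X.T @ Y / len(X)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if scale:
        var = (X**2).sum() / len(X)
        s = float(np.trace(np.diag(S) @ D) / var)
    else:
        s = 1.0
    t = tgt_c - s * R @ src_c
    return R, t, s


def _check_rank(points: np.ndarray) -> None:
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if len(points) < 3 or s[1] <= 1e-9 * max(s[0], 1e-30):
        raise RegistrationError("source points are collinear or degenerate (rank < 2)")


@dataclass
class ICPResult:
    transform: RigidTransform
    rms: float
    n_iter: int
    converged: bool
    rms_history: np.ndarray = field(default=None)
    scale: float = 1.0


def icp_align(
    source: np.ndarray,
    target,
    max_iter: int = 100,
    rel_tol: float = 1e-6,
    with_scale: bool = False,
) -> ICPResult:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    ``target`` may be a point array or a :class:`SurfaceMesh` (its vertices
    are used).  Terminates when the relative RMS change drops below
    ``rel_tol`` or after ``max_iter`` iterations (``converged=False``).
    """
    source = np.asarray(source, dtype=float)
    if isinstance(target, SurfaceMesh):
        target = target.vertices
    target = np.asarray(target, dtype=float)
    _check_rank(source)
    _check_rank(target)

    tree = cKDTree(target)
    current = RigidTransform.identity()
    scale_total = 1.0
    moved = source
    prev_rms = np.inf
    history = []
    converged = False
    it = 0
    # absolute floor: an RMS at machine precision relative to the data
    # extent counts as converged even if it still jitters relatively
    extent = float(np.sqrt(((target - target.mean(axis=0)) ** 2).sum(axis=1).mean()))
    for it in range(1, max_iter + 1):
        dist, idx = tree.query(moved)
        rms = float(np.sqrt((dist**2).mean()))
        history.append(rms)
        if rms <= 1e-10 * max(extent, 1e-30) or (
            prev_rms < np.inf and abs(prev_rms - rms) <= rel_tol * max(prev_rms, 1e-30)
        ):
            converged = True
            break
        prev_rms = rms
        R, t, s = kabsch(moved, target[idx], scale=with_scale)
        step = RigidTransform(R, t)
        moved = s * moved @ R.T + t
        scale_total *= s
        current = RigidTransform(
            step.rotation @ current.rotation,
            s * step.rotation @ current.translation + step.translation,
        )
    dist, _ = tree.query(moved)
    rms = float(np.sqrt((dist**2).mean()))
    return ICPResult(
        transform=current,
        rms=rms,
        n_iter=it,
        converged=converged,
        rms_history=np.array(history),
        scale=scale_total,
    )


def rbf_interpolate(
    sites: np.ndarray,
    values: np.ndarray,
    queries: np.ndarray,
    kernel: str = "thin-plate",
    smoothing: float = 0.0,
    max_sites: int = 4000,
    seed: int = 0,
) -> np.ndarray:
    """RBF interpolation with an affine polynomial term.

    With ``smoothing=0`` the interpolant reproduces the site values exactly
    and any kernel reproduces affine fields exactly (the polynomial tail
    carries them).  If the site count exceeds ``max_sites`` a seeded uniform
    subsample is used (cubic solve cost control); this is recorded by a
    warning.
    """
    sites = np.asarray(sites, dtype=float)
    values = np.asarray(values, dtype=float)
    queries = np.asarray(queries, dtype=float)
    if kernel not in _KERNELS:
        raise ValueError(f"kernel must be one of {sorted(_KERNELS)}")
    if len(sites) < 4:
        raise ValueError("need at least 4 sites")
    c = sites - sites.mean(axis=0)
    sv = np.linalg.svd(c, compute_uv=False)
    if sv[2] <= 1e-9 * max(sv[0], 1e-30):
        raise ValueError("sites are coplanar; the affine system is singular")
    if smoothing == 0.0:
        d, _ = cKDTree(sites).query(sites, k=2)
        if d[:, 1].min() <= 1e-12:
            raise ValueError(
                "duplicate sites with smoothing = 0 make the RBF system singular; "
                "set smoothing > 0"
            )
    if len(sites) > max_sites:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(sites), size=max_sites, replace=False)
        sites, values = sites[pick], values[pick]
        warnings.warn(
            f"RBF sites subsampled to {max_sites} (seeded uniform)", stacklevel=2
        )
    kwargs = {}
    if kernel == "gaussian":
        # shape parameter from the median site spacing
        d, _ = cKDTree(sites).query(sites, k=2)
        kwargs["epsilon"] = 1.0 / max(np.median(d[:, 1]), 1e-12)
    interp = RBFInterpolator(
        sites, values, kernel=_KERNELS[kernel], smoothing=smoothing, degree=1, **kwargs
    )
    return interp(queries)


def map_fields_to_mesh(
    cfd_mesh: SurfaceMesh,
    emap_points: np.ndarray = None,
    emap_bv: np.ndarray = None,
    cmr_points: np.ndarray = None,
    cmr_iir: np.ndarray = None,
    kernel: str = "thin-plate",
    smoothing: float = 1e-8,
    max_sites: int = 4000,
    seed: int = 0,
) -> tuple[ScalarField | None, ScalarField | None]:
    """Align each source point set to the hemodynamic mesh and transfer its
    values onto the mesh vertices (ICP, then RBF).

    The hemodynamic mesh is the basis of the transform: sources are moved,
    the mesh never is.  Returns (BV, IIR) fields with provenance metadata
    (transform, kernel, smoothing, site count); either may be None when the
    corresponding source is absent.
    """
    results = []
    for pts, vals, name, units in (
        (emap_points, emap_bv, "BV", "mV"),
        (cmr_points, cmr_iir, "IIR", ""),
    ):
        if pts is None:
            results.append(None)
            continue
        pts = np.asarray(pts, dtype=float)
        vals = np.asarray(vals, dtype=float)
        if len(pts) < max(10, 0.01 * cfd_mesh.n_vertices):
            warnings.warn(
                f"only {len(pts)} {name} sites on a {cfd_mesh.n_vertices}-vertex mesh; "
                "interpolation will be very smooth",
                stacklevel=2,
            )
        icp = icp_align(pts, cfd_mesh.vertices)
        aligned = icp.transform.apply(pts)
        mapped = rbf_interpolate(
            aligned,
            vals,
            cfd_mesh.vertices,
            kernel=kernel,
            smoothing=smoothing,
            max_sites=max_sites,
            seed=seed,
        )
        results.append(
            ScalarField(
                mapped,
                name=name,
                units=units,
                meta={
                    "icp_rms": icp.rms,
                    "icp_iterations": icp.n_iter,
                    "transform_rotation": icp.transform.rotation.tolist(),
                    "transform_translation": icp.transform.translation.tolist(),
                    "kernel": kernel,
                    "smoothing": smoothing,
                    "n_sites": int(len(pts)),
                },
            )
        )
    return results[0], results[1]
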