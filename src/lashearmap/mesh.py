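"""Triangulated left-atrial surface meshes with anatomical labels.

The :class:`SurfaceMesh` is the geometric substrate shared by every stage of
the pipeline: the shear indices, the blood-age sampling, the field mapping and
the 2D unfolding all live on its vertices.  Coordinates are millimetres
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

#: Anatomical label classes.  Body-wall sectors first, then the appendage,
#: the four pulmonary veins and the mitral rim.
LABELS = {
    "body": 0,
    "roof": 1,
    "posterior": 2,
    "anterior": 3,
    "lateral": 4,
    "septal": 5,
    "floor": 6,
    "appendage": 7,
    "LSPV": 8,
    "LIPV": 9,
    "RSPV": 10,
    "RIPV": 11,
    "mitral_rim": 12,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
PV_LABELS = ("LSPV", "LIPV", "RSPV", "RIPV")


class MeshTopologyError(ValueError):
    """Raised when a mesh violates a manifoldness/topology precondition."""


@dataclass
class SurfaceMesh:
    """Labeled triangulated surface.

    Parameters
    ----------
    vertices : (N, 3) float array, mm
    triangles : (M, 3) int array, 0-based vertex indices
    vertex_labels : (N,) int array of :data:`LABELS` codes
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_labels: np.ndarray = field(default=None)
    #: for meshes extracted from a parent (clipping), the parent vertex index
    #: of each retained vertex; None for meshes built from scratch
    parent_indices: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertex_labels is None:
            self.vertex_labels = np.zeros(len(self.vertices), dtype=np.int64)
        else:
            self.vertex_labels = np.asarray(self.vertex_labels, dtype=np.int64)
        if len(self.vertex_labels) != len(self.vertices):
            raise ValueError("vertex_labels length must equal vertex count")

    # ------------------------------------------------------------------
    # basic quantities
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def copy(self) -> "SurfaceMesh":
        return replace(
            self,
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            vertex_labels=self.vertex_labels.copy(),
        )

    def directed_edges(self) -> np.ndarray:
        """All 3M directed edges in face order (u, v)."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def undirected_edges(self) -> np.ndarray:
        """Unique undirected edges, sorted pairs, shape (E, 2)."""
        de = np.sort(self.directed_edges(), axis=1)
        return np.unique(de, axis=0)

    def euler_characteristic(self) -> int:
        return self.n_vertices - len(self.undirected_edges()) + self.n_triangles

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def mean_edge_length(self) -> float:
        e = self.undirected_edges()
        return float(
            np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1).mean()
        )

    # ------------------------------------------------------------------
    # topology
    def check_manifold(self) -> None:
        """Every edge must be shared by at most two triangles."""
        de = np.sort(self.directed_edges(), axis=1)
        _, counts = np.unique(de, axis=0, return_counts=True)
        if (counts > 2).any():
            raise MeshTopologyError("non-manifold edge shared by >2 triangles")

    def boundary_directed_edges(self) -> np.ndarray:
        """Directed edges (u, v) appearing in exactly one face, in face order."""
        de = self.directed_edges()
        key = np.sort(de, axis=1)
        uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return de[counts[inv] == 1]

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex-index loops of the open boundaries.

        Each loop follows the directed boundary edges as they occur in the
        faces, so loop orientation is consistent with the triangle winding.
        """
        bde = self.boundary_directed_edges()
        nxt = {}
        for u, v in bde:
            if int(u) in nxt:
                raise MeshTopologyError("boundary is not a disjoint union of simple loops")
            nxt[int(u)] = int(v)
        loops = []
        visited = set()
        for start in sorted(nxt):
            if start in visited:
                continue
            loop = [start]
            visited.add(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                visited.add(cur)
                cur = nxt[cur]
            loops.append(np.array(loop, dtype=np.int64))
        return loops

    # ------------------------------------------------------------------
    # differential quantities
    def vertex_normals(self) -> np.ndarray:
        """Outward unit vertex normals (area-weighted, trimesh convention)."""
        tm = self.to_trimesh()
        n = np.array(tm.vertex_normals, dtype=float)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return n / norm

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    # ------------------------------------------------------------------
    # editing helpers
    def submesh_from_vertex_mask(self, keep: np.ndarray) -> "SurfaceMesh":
        """Keep faces whose three vertices are all in ``keep``; reindex."""
        keep = np.asarray(keep, dtype=bool)
        face_keep = keep[self.triangles].all(axis=1)
        used = np.zeros(self.n_vertices, dtype=bool)
        used[self.triangles[face_keep]] = True
        new_index = -np.ones(self.n_vertices, dtype=np.int64)
        new_index[used] = np.arange(used.sum())
        return SurfaceMesh(
            vertices=self.vertices[used],
            triangles=new_index[self.triangles[face_keep]],
            vertex_labels=self.vertex_labels[used],
            parent_indices=np.where(used)[0],
        )

    def label_name(self, code: int) -> str:
        return LABEL_NAMES[int(code)]

    def labels_present(self) -> set[str]:
        return {LABEL_NAMES[c] for c in np.unique(self.vertex_labels)}


def loop_best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane of a point loop (SVD)."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c)
    return c, vt[2]


def loop_plane_area(points: np.ndarray) -> float:
    """Area of a closed polyline projected onto its best-fit plane.

    Vector shoelace formula: A = 0.5 |sum (v_i - c) x (v_{i+1} - c) . n|.
    """
    c, n = loop_best_fit_plane(points)
    p = points - c
    cross = np.cross(p, np.roll(p, -1, axis=0))
    return float(abs(cross.sum(axis=0) @ n) / 2.0)
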