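import numpy as np
import pytest

from lashearmap.geometry import build_idealized_atrium, clip_pulmonary_veins
from lashearmap.mesh import LABELS, SurfaceMesh
from lashearmap.template import build_template, template_from_unfolded
from lashearmap.unfolding import assign_regions, unfold_to_2d


@pytest.fixture(scope="session")
def atrium():
    """Coarse synthetic atrium (~1.2k vertices), shared across tests."""
    return build_idealized_atrium(resolution=3.5, seed=0)


@pytest.fixture(scope="session")
def atrium_medium():
    """Mid-resolution atrium (~4k vertices)."""
    return build_idealized_atrium(resolution=2.0, seed=0)


@pytest.fixture(scope="session")
def atrium_fine():
    """Standard-scale atrium (~16k vertices) for sampling-accuracy checks."""
    return build_idealized_atrium(resolution=1.0, seed=0)


@pytest.fixture(scope="session")
def clipped(atrium):
    return clip_pulmonary_veins(atrium)


@pytest.fixture(scope="session")
def unfolded(clipped):
    """(UnfoldedMap with regions, fitted Template2D) for the coarse atrium."""
    unf = unfold_to_2d(clipped, build_template())
    tpl = template_from_unfolded(unf.uv, clipped.vertex_labels, LABELS)
    return assign_regions(unf, tpl), tpl


def flat_disk_mesh(n_rings=10, n_ang=32, radius=1.0):
    """Triangulated planar disk with the rim labeled as the mitral annulus."""
    verts = [[0.0, 0.0, 0.0]]
    for r in range(1, n_rings + 1):
        rad = radius * r / n_rings
        for a in range(n_ang):
            th = 2 * np.pi * a / n_ang
            verts.append([rad * np.cos(th), rad * np.sin(th), 0.0])
    faces = []
    for a in range(n_ang):
        faces.append([0, 1 + a, 1 + (a + 1) % n_ang])

    def vid(r, a):
        return 1 + (r - 1) * n_ang + a % n_ang

    for r in range(1, n_rings):
        for a in range(n_ang):
            faces.append([vid(r, a), vid(r + 1, a), vid(r + 1, a + 1)])
            faces.append([vid(r, a), vid(r + 1, a + 1), vid(r, a + 1)])
    labels = np.zeros(len(verts), dtype=np.int64)
    labels[-n_ang:] = LABELS["mitral_rim"]
    return SurfaceMesh(np.array(verts, float), np.array(faces), labels)


def open_tube_mesh(radius=5.0, height=10.0, n_ang=48, n_rings=6, scale_xy=(1.0, 1.0)):
    """Cylindrical tube capped at the bottom, open at the top.

    ``scale_xy`` turns the circular cross-section into an ellipse.
    """
    verts = []
    for r in range(n_rings + 1):
        z = height * r / n_rings
        for a in range(n_ang):
            th = 2 * np.pi * a / n_ang
            verts.append(
                [radius * scale_xy[0] * np.cos(th), radius * scale_xy[1] * np.sin(th), z]
            )
    verts.append([0.0, 0.0, 0.0])  # bottom cap apex
    apex = len(verts) - 1
    faces = []

    def vid(r, a):
        return r * n_ang + a % n_ang

    for r in range(n_rings):
        for a in range(n_ang):
            faces.append([vid(r, a), vid(r + 1, a + 1), vid(r + 1, a)])
            faces.append([vid(r, a), vid(r, a + 1), vid(r + 1, a + 1)])
    for a in range(n_ang):
        faces.append([vid(0, a + 1), vid(0, a), apex])
    return SurfaceMesh(np.array(verts, float), np.array(faces))
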