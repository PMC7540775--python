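import numpy as np
import pytest
import trimesh

from endodisp import TriangleMesh

from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def unit_cube() -> TriangleMesh:
    """Axis-aligned unit cube spanning [0, 1]^3 (8 vertices, 12 faces)."""
    box = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return TriangleMesh(np.asarray(box.vertices) + 0.5, np.asarray(box.faces), "cube")


@pytest.fixture
def box_2x3x4() -> TriangleMesh:
    box = trimesh.creation.box(extents=(2.0, 3.0, 4.0))
    return TriangleMesh(np.asarray(box.vertices), np.asarray(box.faces), "box")


@pytest.fixture
def single_triangle() -> TriangleMesh:
    return TriangleMesh(
        np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        np.array([[0, 1, 2]]),
        "tri",
    )


@pytest.fixture
def blob_mesh() -> TriangleMesh:
    """Convex hull of seeded random points: an irregular ~50-triangle mesh."""
    rng = np.random.default_rng(42)
    pts = rng.normal(size=(27, 3))
    hull = trimesh.convex.convex_hull(pts)
    return TriangleMesh(np.asarray(hull.vertices), np.asarray(hull.faces), "blob")


@pytest.fixture
def ellipsoid() -> TriangleMesh:
    """Asymmetric smooth shape (no rotational symmetry axis)."""
    ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
    return TriangleMesh(
        np.asarray(ico.vertices) * np.array([1.0, 1.3, 1.7]),
        np.asarray(ico.faces),
        "ellipsoid",
    )
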