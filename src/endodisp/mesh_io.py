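"""Triangle-mesh containers, STL input, and vertex-colored PLY export.

Brain and endocast surfaces arrive as STL files (binary or ASCII) in
millimetres.  STL stores each facet's vertices independently, so reading
welds duplicate vertices within a small tolerance relative to the bounding
box.  Scalar fields (e.g. an unsigned brain-to-endocast distance map) are
exported as vertex-colored PLY, because STL cannot carry per-vertex data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

__all__ = [
    "TriangleMesh",
    "MeshReport",
    "ScalarField",
    "read_triangle_mesh",
    "write_triangle_mesh",
    "weld_vertices",
    "mesh_summary",
    "write_colored_mesh",
]

#: relative weld tolerance: fraction of the bounding-box diagonal within which
#: STL facet vertices are considered identical
WELD_REL_TOL = 1e-8


class MeshError(ValueError):
    """Contract violation on a mesh operation."""


@dataclass
class TriangleMesh:
    """Indexed triangle surface in millimetres.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        Triplets of vertex indices, counter-clockwise when outward-oriented.
    name : str
        Free-text label (specimen / structure name).
    """

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be an (F, 3) array")
        if not np.isfinite(self.vertices).all():
            raise MeshError("vertex coordinates must be finite")
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise MeshError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Return the (F, 3, 3) array of triangle corner coordinates."""
        return self.vertices[self.faces]

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if not len(self.vertices):
            raise MeshError("empty mesh has no bounds")
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def bbox_diagonal(self) -> float:
        lo, hi = self.bounds()
        return float(np.linalg.norm(hi - lo))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name)


@dataclass
class MeshReport:
    """Validation summary for a mesh: counts, closedness, degeneracies."""

    n_vertices: int
    n_faces: int
    watertight: bool
    n_degenerate_faces: int
    bbox_min: np.ndarray
    bbox_max: np.ndarray


@dataclass
class ScalarField:
    """One finite non-negative value per vertex of an associated mesh (mm)."""

    values: np.ndarray
    field_name: str = "distance_mm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.isfinite(self.values).all():
            raise MeshError("scalar field values must be finite")


def weld_vertices(mesh: TriangleMesh, rel_tol: float = WELD_REL_TOL) -> TriangleMesh:
    """Merge vertices closer than ``rel_tol`` x bounding-box diagonal.

    Idempotent: welding an already-welded mesh returns identical arrays.
    Coordinates are snapped to a grid of pitch ``rel_tol * diagonal``; the
    representative vertex keeps the coordinates of its first occurrence, so
    geometry moves by strictly less than the weld pitch.
    """
    if not len(mesh.vertices):
        return mesh.copy()
    diag = mesh.bbox_diagonal()
    pitch = rel_tol * diag if diag > 0 else rel_tol
    keys = np.round(mesh.vertices / pitch).astype(np.int64)
    _, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    new_vertices = mesh.vertices[first]
    new_faces = inverse[mesh.faces]
    return TriangleMesh(new_vertices, new_faces, mesh.name)


def read_triangle_mesh(
    path, fmt: str = "stl_auto", weld: bool = True, name: Optional[str] = None
) -> TriangleMesh:
    """Read an STL (or PLY) surface into a :class:`TriangleMesh`.

    ``fmt`` is one of ``stl_auto`` (sniff binary vs ASCII from the file
    content), ``stl_ascii``, ``stl_binary``, or ``ply``.  Duplicate facet
    vertices are welded (see :func:`weld_vertices`) unless ``weld=False``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mesh file not found: {path}")
    if fmt not in {"stl_auto", "stl_ascii", "stl_binary", "ply"}:
        raise MeshError(f"unknown mesh format {fmt!r}")
    filetype = "ply" if fmt == "ply" else "stl"
    if fmt in {"stl_ascii", "stl_binary"}:
        _check_stl_dialect(path, fmt)
    try:
        with open(path, "rb") as fh:
            tm = trimesh.load(fh, file_type=filetype, process=False)
    except Exception as exc:  # corrupt/truncated file
        size = path.stat().st_size
        raise IOError(
            f"failed to parse {path} as {filetype} "
            f"(file size {size} bytes): {exc}"
        ) from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshError(f"{path} contains no facets (empty mesh)")
        tm = trimesh.util.concatenate(geoms)
    if tm.faces.shape[0] == 0:
        raise MeshError(f"{path} contains no facets (empty mesh)")
    mesh = TriangleMesh.from_trimesh(tm, name=name if name is not None else path.stem)
    return weld_vertices(mesh) if weld else mesh


def _check_stl_dialect(path: Path, fmt: str) -> None:
    """Verify the file matches the explicitly requested STL dialect."""
    with open(path, "rb") as fh:
        head = fh.read(512)
    looks_ascii = head.lstrip()[:5] == b"solid" and b"\x00" not in head
    if fmt == "stl_ascii" and not looks_ascii:
        raise IOError(f"{path}: requested ASCII STL but header is not ASCII")
    if fmt == "stl_binary" and looks_ascii:
        raise IOError(f"{path}: requested binary STL but file looks ASCII")


def write_triangle_mesh(mesh: TriangleMesh, path, fmt: str = "stl_binary") -> Path:
    """Write a mesh as STL (``stl_binary``/``stl_ascii``) or ``ply``."""
    path = Path(path)
    tm = mesh.to_trimesh()
    if fmt == "stl_binary":
        data = trimesh.exchange.stl.export_stl(tm)
        path.write_bytes(data)
    elif fmt == "stl_ascii":
        text = trimesh.exchange.stl.export_stl_ascii(tm)
        path.write_text(text)
    elif fmt == "ply":
        tm.export(str(path), file_type="ply")
    else:
        raise MeshError(f"unknown mesh format {fmt!r}")
    return path


def degenerate_faces(mesh: TriangleMesh, area_tol: float = 1e-12) -> np.ndarray:
    """Indices of faces with area < ``area_tol`` mm^2 or a repeated vertex."""
    tri = mesh.triangles()
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    repeated = (
        (mesh.faces[:, 0] == mesh.faces[:, 1])
        | (mesh.faces[:, 1] == mesh.faces[:, 2])
        | (mesh.faces[:, 0] == mesh.faces[:, 2])
    )
    return np.flatnonzero((areas < area_tol) | repeated)


def _edge_counts(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return uniq, counts


def open_edge_count(mesh: TriangleMesh) -> int:
    """Number of undirected edges not shared by exactly two faces."""
    if not len(mesh.faces):
        return 0
    _, counts = _edge_counts(mesh.faces)
    return int(np.count_nonzero(counts != 2))


def is_watertight(mesh: TriangleMesh) -> bool:
    """True iff every undirected edge is shared by exactly two faces."""
    return len(mesh.faces) > 0 and open_edge_count(mesh) == 0


def mesh_summary(mesh: TriangleMesh) -> MeshReport:
    """Counts, watertightness (edge incidence) and degeneracy report."""
    if not len(mesh.vertices):
        raise MeshError("cannot summarize an empty mesh")
    lo, hi = mesh.bounds()
    return MeshReport(
        n_vertices=mesh.n_vertices,
        n_faces=mesh.n_faces,
        watertight=is_watertight(mesh),
        n_degenerate_faces=int(len(degenerate_faces(mesh))),
        bbox_min=lo,
        bbox_max=hi,
    )


def write_colored_mesh(
    mesh: TriangleMesh,
    field: ScalarField,
    path,
    value_range: Optional[tuple[float, float]] = None,
    colormap: str = "viridis",
) -> Path:
    """Export ``mesh`` with ``field`` mapped to per-vertex 8-bit RGB as PLY.

    Values are clipped to ``value_range`` before the color lookup.  If the
    range is omitted it defaults to the field's (min, max); a constant field
    maps to ``[0, max(value, 1)]`` so the export is always well defined.  A
    CSV sidecar ``<path>.range.csv`` records ``field_name, lo, hi, colormap``
    so figure color scales are reproducible.
    """
    import matplotlib

    if len(field.values) != mesh.n_vertices:
        raise MeshError(
            f"field length {len(field.values)} != vertex count {mesh.n_vertices}"
        )
    if value_range is None:
        lo, hi = float(field.values.min()), float(field.values.max())
        if lo == hi:
            lo, hi = 0.0, max(hi, 1.0)
    else:
        lo, hi = float(value_range[0]), float(value_range[1])
        if not lo < hi:
            raise MeshError("value_range must satisfy lo < hi")
    cmap = matplotlib.colormaps[colormap]
    normed = (np.clip(field.values, lo, hi) - lo) / (hi - lo)
    rgba = (cmap(normed) * 255).astype(np.uint8)

    path = Path(path)
    tm = mesh.to_trimesh()
    tm.visual.vertex_colors = rgba
    tm.export(str(path), file_type="ply")
    sidecar = path.with_suffix(path.suffix + ".range.csv")
    with open(sidecar, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["field_name", "lo", "hi", "colormap"])
        writer.writerow([field.field_name, repr(lo), repr(hi), colormap])
    return path
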