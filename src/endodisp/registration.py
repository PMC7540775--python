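"""Rigid iterative-closest-point superposition of brain onto endocast.

The superposition is rigid only (rotation + translation, no scaling):
brain and endocast come from the same specimen and scan, so their relative
scale is physical.  Each ICP iteration samples source vertices (seeded,
without replacement), finds each sample's exact nearest point on the
target *surface* (not nearest vertex, which biases distances on coarse
meshes), optionally trims the worst pairs, and solves the closed-form
Kabsch least-squares rotation.  The RMS correspondence distance is
monotone non-increasing after the first iteration because each Kabsch
solve is optimal for its correspondences and re-matching can only shorten
them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .disparity import SurfaceIndex
from .mesh_io import MeshError, TriangleMesh

__all__ = [
    "RigidTransform",
    "IcpParams",
    "IcpResult",
    "kabsch",
    "icp_register",
    "apply_transform",
]


@dataclass
class RigidTransform:
    """Rotation + translation mapping source coordinates into the target frame.

    ``apply`` maps v -> R v + t.  The rotation is proper orthonormal
    (det +1); composition and inversion stay within the group.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-6 or np.linalg.det(self.rotation) < 0:
            raise ValueError(
                "rotation must be proper orthonormal "
                f"(orthonormality residual {err:.2e}, "
                f"det {np.linalg.det(self.rotation):.6f})"
            )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=np.float64)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("rotation axis must be non-zero")
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
        return cls(rot.as_matrix(), np.asarray(translation, dtype=np.float64))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix, row-major, translation in mm."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps({"matrix_4x4_row_major": self.matrix().tolist()}, indent=2)
        )
        return path

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        data = json.loads(Path(path).read_text())
        return cls.from_matrix(np.asarray(data["matrix_4x4_row_major"]))


@dataclass
class IcpParams:
    """ICP settings.

    ``n_sample_points`` source vertices are drawn without replacement per
    run (all vertices if the mesh is smaller); ``trim_fraction`` of the
    worst correspondences may be discarded each iteration for robustness
    to protruding structures.  ``initial_alignment="centroid"`` starts
    from centroid superposition, a safe default when both meshes originate
    in the same scan frame.
    """

    max_iterations: int = 100
    rel_tolerance: float = 1e-6
    n_sample_points: int = 5000
    seed: int = 0
    initial_alignment: str = "centroid"
    trim_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.rel_tolerance <= 0:
            raise ValueError("rel_tolerance must be > 0")
        if self.n_sample_points < 4:
            raise ValueError("n_sample_points must be >= 4")
        if not 0 <= self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.initial_alignment not in {"none", "centroid"}:
            raise ValueError("initial_alignment must be 'none' or 'centroid'")


@dataclass
class IcpResult:
    transform: RigidTransform
    rms_trace: np.ndarray
    converged: bool
    n_iterations: int


def kabsch(source_points: np.ndarray, target_points: np.ndarray) -> RigidTransform:
    """Optimal least-squares rigid superposition of paired point sets.

    Centers both sets, takes the SVD of the cross-covariance, and
    sign-corrects the smallest singular direction so the result is a proper
    rotation (no reflection).  Raises on fewer than 3 pairs or collinear
    source configurations, where the rotation is not determined.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matching (N, 3) arrays")
    if len(src) < 3:
        raise ValueError("kabsch requires at least 3 point pairs")
    src_c = src.mean(axis=0)
    tgt_c = tgt.mean(axis=0)
    h = (src - src_c).T @ (tgt - tgt_c)
    u, s, vt = np.linalg.svd(h)
    # collinear source points leave the rotation about their axis free
    src0 = src - src_c
    sing = np.linalg.svd(src0, compute_uv=False)
    if sing[1] < 1e-12 * max(sing[0], 1.0):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = tgt_c - rotation @ src_c
    return RigidTransform(rotation, translation)


def apply_transform(mesh: TriangleMesh, tf: RigidTransform) -> TriangleMesh:
    """Return a new mesh with every vertex mapped v -> R v + t."""
    return TriangleMesh(tf.apply(mesh.vertices), mesh.faces.copy(), mesh.name)


def icp_register(
    source: TriangleMesh,
    target: TriangleMesh,
    params: IcpParams | None = None,
) -> IcpResult:
    """Register ``source`` onto ``target`` by point-to-surface rigid ICP.

    The returned transform maps source coordinates into the target frame.
    Non-convergence within ``max_iterations`` is reported via
    ``converged=False`` with the full RMS trace, not raised.
    """
    if params is None:
        params = IcpParams()
    if not len(source.vertices) or not len(target.faces):
        raise MeshError("ICP requires non-empty source and target meshes")

    rng = np.random.default_rng(params.seed)
    n = min(params.n_sample_points, len(source.vertices))
    sample_idx = (
        rng.choice(len(source.vertices), size=n, replace=False)
        if n < len(source.vertices)
        else np.arange(len(source.vertices))
    )
    samples = source.vertices[sample_idx]

    if params.initial_alignment == "centroid":
        shift = target.vertices.mean(axis=0) - source.vertices.mean(axis=0)
        current = RigidTransform(np.eye(3), shift)
    else:
        current = RigidTransform.identity()

    index = SurfaceIndex(target)
    n_keep = max(3, int(np.ceil(n * (1.0 - params.trim_fraction))))
    # below this scale the RMS is floating-point noise, not misalignment
    rms_floor = 1e-12 * target.bbox_diagonal()
    rms_trace: list[float] = []
    converged = False

    for _ in range(params.max_iterations):
        moved = current.apply(samples)
        closest, dist = index.query(moved)
        if params.trim_fraction > 0 and n_keep < n:
            keep = np.argsort(dist)[:n_keep]
        else:
            keep = slice(None)
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        rms_trace.append(rms)
        if rms <= rms_floor:
            converged = True
            break
        if len(rms_trace) >= 2:
            prev = rms_trace[-2]
            if abs(prev - rms) <= params.rel_tolerance * max(prev, 1e-300):
                converged = True
                break
        step = kabsch(moved[keep], closest[keep])
        current = step.compose(current)

    return IcpResult(
        transform=current,
        rms_trace=np.asarray(rms_trace),
        converged=converged,
        n_iterations=len(rms_trace),
    )
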