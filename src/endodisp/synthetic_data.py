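"""Phantom brain/endocast pairs and label volumes with analytic ground truth.

Real specimen meshes come from manual segmentation of contrast-stained
CT / MRI scans and are rarely redistributable, so every downstream stage
is validated on schematic phantoms whose volumes, surface gaps, overlap
and per-slice areas are known in closed form: nested icospheres for the
brain-in-endocast geometry, a shrunken capsule for regionally varying
disparity, and block/cylinder/taper voxel phantoms for cross-sectional
area.  All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import trimesh

from .csa import LabelVolume
from .mesh_io import MeshError, TriangleMesh
from .registration import RigidTransform, apply_transform

__all__ = [
    "SyntheticPair",
    "PairTruth",
    "make_sphere",
    "make_nested_pair",
    "apply_rigid_perturbation",
    "make_brain_endocast_phantom",
    "make_label_phantom",
]

SPHERE_VOLUME = lambda r: 4.0 / 3.0 * np.pi * r**3  # noqa: E731


@dataclass
class PairTruth:
    """Analytic ground truth recorded with a synthetic pair."""

    brain_volume: float
    endocast_volume: float
    #: every directed point-to-surface distance, where constant (concentric)
    directed_distance: Optional[float] = None
    #: symmetric Hausdorff distance, where analytic
    max_absolute: Optional[float] = None
    #: Dice for nested solids: 2 V_in / (V_in + V_out)
    dice: Optional[float] = None
    applied_transform: Optional[RigidTransform] = None
    #: region name -> expected radial gap (mm), for regional phantoms
    region_gap: dict[str, float] = field(default_factory=dict)


@dataclass
class SyntheticPair:
    brain: TriangleMesh
    endocast: TriangleMesh
    truth: PairTruth
    seed: int = 0


def make_sphere(
    radius: float, center=(0.0, 0.0, 0.0), subdivisions: int = 3, name: str = "sphere"
) -> TriangleMesh:
    """Watertight icosphere: subdivided icosahedron projected to the radius.

    ``subdivisions=0`` is the bare icosahedron (12 vertices, 20 faces);
    each level quadruples the face count.  Every vertex lies at exactly
    ``radius`` from ``center`` up to floating point.
    """
    if radius <= 0:
        raise MeshError("radius must be positive")
    if not 0 <= subdivisions <= 6:
        raise MeshError("subdivisions must be in [0, 6]")
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    vertices = np.asarray(ico.vertices) + np.asarray(center, dtype=np.float64)
    return TriangleMesh(vertices, np.asarray(ico.faces), name)


def make_nested_pair(
    outer_radius: float,
    inner_radius: float,
    offset=(0.0, 0.0, 0.0),
    subdivisions: int = 4,
    seed: int = 0,
) -> SyntheticPair:
    """Sphere-in-sphere phantom for the nested brain-in-endocast geometry.

    The inner sphere (brain) is centered at ``offset`` inside the outer
    sphere (endocast) at the origin; containment is required.  Recorded
    truth: analytic sphere volumes; for the concentric case every directed
    point-to-surface distance equals ``outer_radius - inner_radius``; the
    symmetric maximum absolute distance is
    ``outer_radius - inner_radius + |offset|`` (attained anti-parallel to
    the offset); Dice for nested solids is 2 V_in / (V_in + V_out).
    """
    offset = np.asarray(offset, dtype=np.float64)
    off = float(np.linalg.norm(offset))
    if inner_radius + off >= outer_radius:
        raise MeshError(
            "inner sphere must be strictly contained: "
            f"inner_radius + |offset| = {inner_radius + off:.6g} "
            f">= outer_radius = {outer_radius:.6g}"
        )
    endocast = make_sphere(outer_radius, subdivisions=subdivisions, name="endocast")
    brain = make_sphere(
        inner_radius, center=offset, subdivisions=subdivisions, name="brain"
    )
    v_in = SPHERE_VOLUME(inner_radius)
    v_out = SPHERE_VOLUME(outer_radius)
    truth = PairTruth(
        brain_volume=v_in,
        endocast_volume=v_out,
        directed_distance=(outer_radius - inner_radius) if off == 0 else None,
        max_absolute=outer_radius - inner_radius + off,
        dice=2.0 * v_in / (v_in + v_out),
    )
    return SyntheticPair(brain=brain, endocast=endocast, truth=truth, seed=seed)


def apply_rigid_perturbation(
    mesh: TriangleMesh,
    angle_deg: float,
    axis=None,
    translation=(0.0, 0.0, 0.0),
    seed: int = 0,
) -> tuple[TriangleMesh, RigidTransform]:
    """Apply a known rigid motion; returns (moved mesh, exact transform).

    ``axis=None`` draws a seeded random unit axis.  The inverse of the
    returned transform restores the input mesh exactly, which makes the
    pair a ground truth for registration recovery.
    """
    if axis is None:
        rng = np.random.default_rng(seed)
        vec = rng.normal(size=3)
        axis = vec / np.linalg.norm(vec)
    tf = RigidTransform.from_axis_angle(axis, angle_deg, translation)
    return apply_transform(mesh, tf), tf


def make_brain_endocast_phantom(
    profile: str = "uniform",
    shrink_factor: float = 0.8,
    noise_sd: float = 0.0,
    radius: float = 10.0,
    length: float = 30.0,
    seed: int = 0,
) -> SyntheticPair:
    """Capsule endocast with a regionally shrunken brain inside.

    The endocast is a watertight capsule with its long axis along x
    (total length ``length``, cap radius ``radius``).  The brain takes
    each endocast vertex and scales its radial component (distance to the
    capsule core segment) by ``shrink_factor`` — everywhere for
    ``profile="uniform"``, or only anterior (x below the midplane) /
    posterior of it for the asymmetric profiles — then adds seeded
    Gaussian noise of SD ``noise_sd`` along the outward radial direction.
    Recorded truth holds the expected radial gap per region:
    ``(1 - shrink_factor) * radius`` in shrunken regions, 0 elsewhere.
    """
    if not 0 < shrink_factor <= 1:
        raise MeshError("shrink_factor must be in (0, 1]")
    if noise_sd < 0:
        raise MeshError("noise_sd must be >= 0")
    if profile not in {"uniform", "anterior_shrink", "posterior_shrink"}:
        raise MeshError(f"unknown profile {profile!r}")
    core_half = max(length / 2.0 - radius, 0.0)
    cap = trimesh.creation.capsule(radius=radius, height=2 * core_half)
    # rotate the z-axis capsule onto the x axis (proper rotation)
    rot = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
    verts = np.asarray(cap.vertices) @ rot.T
    endocast = TriangleMesh(verts, np.asarray(cap.faces), "endocast")

    axis_point = verts.copy()
    axis_point[:, 0] = np.clip(verts[:, 0], -core_half, core_half)
    axis_point[:, 1] = 0.0
    axis_point[:, 2] = 0.0
    radial = verts - axis_point
    rnorm = np.linalg.norm(radial, axis=1, keepdims=True)
    rdir = np.where(rnorm > 0, radial / np.where(rnorm == 0, 1.0, rnorm), 0.0)

    anterior = verts[:, 0] < 0.0
    factors = np.ones(len(verts))
    if profile == "uniform":
        factors[:] = shrink_factor
    elif profile == "anterior_shrink":
        factors[anterior] = shrink_factor
    else:
        factors[~anterior] = shrink_factor

    brain_verts = axis_point + factors[:, None] * radial
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=len(verts))
        brain_verts = brain_verts + noise[:, None] * rdir
    brain = TriangleMesh(brain_verts, endocast.faces.copy(), "brain")

    gap = (1.0 - shrink_factor) * radius
    if profile == "uniform":
        region_gap = {"anterior": gap, "posterior": gap}
    elif profile == "anterior_shrink":
        region_gap = {"anterior": gap, "posterior": 0.0}
    else:
        region_gap = {"anterior": 0.0, "posterior": gap}

    cyl_r = radius
    v_cyl = lambda r: np.pi * r**2 * (2 * core_half) + SPHERE_VOLUME(r)  # noqa: E731
    truth = PairTruth(
        brain_volume=v_cyl(shrink_factor * cyl_r) if profile == "uniform" else np.nan,
        endocast_volume=v_cyl(cyl_r),
        region_gap=region_gap,
    )
    return SyntheticPair(brain=brain, endocast=endocast, truth=truth, seed=seed)


def anterior_mask(mesh: TriangleMesh) -> np.ndarray:
    """Vertices anterior of the bounding-box x midplane."""
    lo, hi = mesh.bounds()
    mid = 0.5 * (lo[0] + hi[0])
    return mesh.vertices[:, 0] < mid


def make_label_phantom(
    shape: str,
    dims: tuple[int, int, int] = (32, 32, 8),
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.2),
    label: int = 1,
    seed: int = 0,
    block_extent: tuple[int, int] = (10, 10),
    radius_vox: float = 10.0,
    taper_base_area: float = 1.0,
) -> tuple[LabelVolume, np.ndarray]:
    """Voxel phantom with analytic per-slice areas; returns (volume, truth).

    ``dims`` is (nx, ny, nz); the labels array is stored (z, y, x).
    Shapes:

    - ``block``: a ``block_extent`` rectangle in every z slice —
      constant area ``bx * by * dx * dy``.
    - ``cylinder``: a digitized disc of radius ``radius_vox`` voxels
      (z axis) in every slice; truth is the exact pixel count times the
      pixel area, which approaches pi r^2 as the radius grows.
    - ``taper``: slice k carries (k+1) x round(taper_base_area / (dx dy))
      labeled voxels, a linear area ramp that is exact by construction.
    - ``empty``: no labeled voxels.

    The truth array holds one area (mm^2) per z slice.
    """
    nx, ny, nz = dims
    if min(dims) < 1:
        raise MeshError("dims must be positive")
    dx, dy, dz = spacing
    if min(spacing) <= 0:
        raise MeshError("spacing must be positive")
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    pixel_area = dx * dy

    if shape == "block":
        bx, by = block_extent
        if bx > nx or by > ny:
            raise MeshError("block_extent exceeds in-plane dims")
        x0 = (nx - bx) // 2
        y0 = (ny - by) // 2
        labels[:, y0 : y0 + by, x0 : x0 + bx] = label
        truth = np.full(nz, bx * by * pixel_area)
    elif shape == "cylinder":
        cx = (nx - 1) / 2.0
        cy = (ny - 1) / 2.0
        yy, xx = np.mgrid[0:ny, 0:nx]
        disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_vox**2
        labels[:, disc] = label
        truth = np.full(nz, int(disc.sum()) * pixel_area)
    elif shape == "taper":
        per_step = int(round(taper_base_area / pixel_area))
        truth = np.empty(nz)
        for k in range(nz):
            n_vox = (k + 1) * per_step
            if n_vox > nx * ny:
                raise MeshError("taper phantom does not fit in-plane dims")
            flat = labels[k].reshape(-1)
            flat[:n_vox] = label
            truth[k] = n_vox * pixel_area
    elif shape == "empty":
        truth = np.zeros(nz)
    else:
        raise MeshError(f"unknown phantom shape {shape!r}")

    volume = LabelVolume(labels, spacing, {label: shape} if shape != "empty" else {})
    return volume, truth
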