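"""Exact point-to-surface distances and symmetric distance summaries."""

import numpy as np
import pytest

from endodisp import (
    RigidTransform,
    TriangleMesh,
    apply_transform,
    distance_map_on_endocast,
    distance_summary,
    make_brain_endocast_phantom,
    make_nested_pair,
    make_sphere,
)
from endodisp.disparity import (
    SurfaceIndex,
    closest_point_on_triangles,
    directed_distances,
    directed_distances_bruteforce,
    sample_surface_points,
)
from endodisp.mesh_io import MeshError
from endodisp.synthetic_data import anterior_mask


class TestDirectedDistances:
    def test_target_vertices_have_zero_distance(self, blob_mesh):
        d = directed_distances(blob_mesh.vertices, blob_mesh)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_perpendicular_offset_from_face_interior(self, single_triangle):
        bary = single_triangle.vertices.mean(axis=0)
        query = bary + np.array([0.0, 0.0, 0.7])  # normal is +z
        d = directed_distances(query[None, :], single_triangle)
        assert d[0] == pytest.approx(0.7, abs=1e-12)

    def test_matches_bruteforce_oracle(self, blob_mesh):
        rng = np.random.default_rng(0)
        queries = rng.uniform(-3, 3, size=(500, 3))
        fast = directed_distances(queries, blob_mesh)
        slow = directed_distances_bruteforce(queries, blob_mesh)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_matches_trimesh_oracle(self, blob_mesh):
        # independent implementation of the same primitive
        from trimesh.proximity import closest_point_naive

        rng = np.random.default_rng(1)
        queries = rng.uniform(-2, 2, size=(100, 3))
        _, d_ref, _ = closest_point_naive(blob_mesh.to_trimesh(), queries)
        mine = directed_distances(queries, blob_mesh)
        np.testing.assert_allclose(mine, d_ref, atol=1e-9)

    def test_edge_and_vertex_regions(self, single_triangle):
        # beyond vertex A: closest feature is the vertex itself
        d = directed_distances(np.array([[-1.0, -1.0, 0.0]]), single_triangle)
        assert d[0] == pytest.approx(np.sqrt(2.0), abs=1e-12)
        # past edge AB: closest feature is a point on the edge
        d = directed_distances(np.array([[0.5, -2.0, 0.0]]), single_triangle)
        assert d[0] == pytest.approx(2.0, abs=1e-12)

    def test_empty_target_rejected(self):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            directed_distances(np.zeros((1, 3)), empty)

    def test_paired_primitive_handles_degenerate_layouts(self):
        # near-degenerate sliver triangle: distance still finite and correct
        tri = np.array([[[0, 0, 0], [1, 0, 0], [0.5, 1e-13, 0]]], dtype=float)
        _, d = closest_point_on_triangles(np.array([[0.5, 1.0, 0.0]]), tri)
        assert d[0] == pytest.approx(1.0, abs=1e-9)


class TestDistanceSummary:
    def test_identical_meshes_all_zero(self, blob_mesh):
        ds = distance_summary(blob_mesh, blob_mesh)
        assert ds.symmetric_mean == pytest.approx(0.0, abs=1e-12)
        assert ds.max_absolute == pytest.approx(0.0, abs=1e-12)

    def test_concentric_spheres_gap(self):
        pair = make_nested_pair(2.0, 1.0, subdivisions=3)
        ds = distance_summary(pair.brain, pair.endocast)
        assert ds.symmetric_mean == pytest.approx(1.0, abs=0.01)
        assert ds.max_absolute == pytest.approx(1.0, abs=0.01)

    def test_offset_spheres_hausdorff(self):
        pair = make_nested_pair(2.0, 1.0, offset=(0.5, 0.0, 0.0), subdivisions=3)
        ds = distance_summary(pair.brain, pair.endocast)
        assert ds.max_absolute == pytest.approx(pair.truth.max_absolute, abs=0.02)

    def test_symmetry_swaps_directed_blocks(self, blob_mesh):
        other = make_sphere(0.5, center=(2.0, 0.0, 0.0), subdivisions=2)
        ab = distance_summary(blob_mesh, other)
        ba = distance_summary(other, blob_mesh)
        assert ab.mean_a_to_b == ba.mean_b_to_a
        assert ab.max_a_to_b == ba.max_b_to_a
        assert ab.symmetric_mean == ba.symmetric_mean
        assert ab.max_absolute == ba.max_absolute

    def test_rigid_invariance_of_summary(self):
        pair = make_nested_pair(2.0, 1.0, offset=(0.3, 0.2, 0.0), subdivisions=2)
        base = distance_summary(pair.brain, pair.endocast)
        tf = RigidTransform.from_axis_angle((1, 2, 3), 35.0, (4.0, -1.0, 2.0))
        moved = distance_summary(
            apply_transform(pair.brain, tf), apply_transform(pair.endocast, tf)
        )
        for attr in (
            "mean_a_to_b",
            "mean_b_to_a",
            "symmetric_mean",
            "max_a_to_b",
            "max_b_to_a",
            "max_absolute",
        ):
            assert getattr(moved, attr) == pytest.approx(
                getattr(base, attr), abs=1e-9
            )

    def test_summary_invariants(self):
        pair = make_nested_pair(2.0, 1.0, offset=(0.4, 0.0, 0.0), subdivisions=2)
        ds = distance_summary(pair.brain, pair.endocast)
        assert ds.max_absolute == max(ds.max_a_to_b, ds.max_b_to_a)
        assert (
            min(ds.mean_a_to_b, ds.mean_b_to_a)
            <= ds.symmetric_mean
            <= max(ds.mean_a_to_b, ds.mean_b_to_a)
        )

    def test_surface_sampling_refinement_is_cauchy(self):
        pair = make_nested_pair(2.0, 1.0, offset=(0.3, 0.0, 0.0), subdivisions=3)
        means = [
            distance_summary(
                pair.brain,
                pair.endocast,
                sampling="surface_uniform",
                n_surface_samples=n,
                seed=0,
            ).symmetric_mean
            for n in (5000, 10_000, 20_000)
        ]
        assert abs(means[1] - means[0]) < 0.02
        assert abs(means[2] - means[1]) < 0.01

    def test_surface_samples_lie_on_surface(self, blob_mesh):
        pts = sample_surface_points(blob_mesh, 2000, seed=3)
        d = directed_distances(pts, blob_mesh)
        np.testing.assert_allclose(d, 0.0, atol=1e-9)

    def test_invalid_sampling_arguments(self, blob_mesh):
        with pytest.raises(MeshError):
            distance_summary(blob_mesh, blob_mesh, sampling="nope")
        with pytest.raises(MeshError):
            sample_surface_points(blob_mesh, 0)


class TestDistanceMap:
    def test_identical_meshes_zero_field(self, blob_mesh):
        field = distance_map_on_endocast(blob_mesh, blob_mesh)
        np.testing.assert_allclose(field.values, 0.0, atol=1e-12)

    def test_concentric_spheres_constant_field(self):
        pair = make_nested_pair(2.0, 1.0, subdivisions=3)
        field = distance_map_on_endocast(pair.brain, pair.endocast)
        np.testing.assert_allclose(field.values, 1.0, atol=0.01)

    def test_map_bounded_by_directed_max(self):
        pair = make_nested_pair(2.0, 1.0, offset=(0.3, 0.1, 0.0), subdivisions=2)
        ds = distance_summary(pair.brain, pair.endocast)
        field = distance_map_on_endocast(pair.brain, pair.endocast)
        assert field.values.max() <= ds.max_b_to_a + 1e-12

    def test_anterior_shrink_ordering(self):
        pair = make_brain_endocast_phantom("anterior_shrink", shrink_factor=0.7)
        field = distance_map_on_endocast(pair.brain, pair.endocast)
        mask = anterior_mask(pair.endocast)
        assert field.values[mask].mean() > field.values[~mask].mean()


class TestSurfaceIndexCover:
    def test_cover_preserves_exactness_on_mixed_triangle_sizes(self):
        # capsule mixes small cap faces and large cylinder faces
        pair = make_brain_endocast_phantom("uniform", shrink_factor=0.9)
        rng = np.random.default_rng(4)
        queries = rng.uniform(-20, 20, size=(200, 3))
        fast = directed_distances(queries, pair.endocast)
        slow = directed_distances_bruteforce(queries, pair.endocast)
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_index_reuse_matches_fresh_queries(self, blob_mesh):
        idx = SurfaceIndex(blob_mesh)
        rng = np.random.default_rng(5)
        q = rng.uniform(-2, 2, size=(50, 3))
        np.testing.assert_array_equal(
            directed_distances(q, idx), directed_distances(q, blob_mesh)
        )
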