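"""Seeding, tessellation and extrusion of the spherical monolayer shell."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoidvm import shell_builder as sb
from organoidvm.errors import InvalidConfigurationError, TessellationDegeneracyError


# ---------------------------------------------------------------------------
# Fibonacci seeding
# ---------------------------------------------------------------------------

class TestFibonacciSeeds:
    def test_rejects_fewer_than_four_seeds(self):
        with pytest.raises(InvalidConfigurationError):
            sb.fibonacci_seeds(1)

    def test_jitter_free_lattice_formula(self):
        s = sb.fibonacci_seeds(4, 0.0)
        assert len(s.unit_vectors) == 4
        # first point: z = 1 - 2*(0.5)/4 = 0.75
        assert s.unit_vectors[0, 2] == pytest.approx(0.75, abs=1e-15)
        i = np.arange(4)
        z = 1 - 2 * (i + 0.5) / 4
        r = np.sqrt(1 - z**2)
        theta = i * np.pi * (3 - np.sqrt(5))
        expect = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
        np.testing.assert_allclose(s.unit_vectors, expect, atol=1e-15)

    def test_lattice_min_angular_separation(self):
        pts = sb.fibonacci_seeds(100, 0.0).unit_vectors
        # brute force over all pairs
        cosang = np.clip(pts @ pts.T, -1, 1)
        np.fill_diagonal(cosang, -1)
        assert np.arccos(cosang.max()) > 0.1

    def test_jittered_seeds_normalized_and_deterministic(self):
        a = sb.fibonacci_seeds(400, 0.2, rng_seed=42)
        b = sb.fibonacci_seeds(400, 0.2, rng_seed=42)
        assert len(a.unit_vectors) == 400
        np.testing.assert_allclose(
            np.linalg.norm(a.unit_vectors, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(a.unit_vectors, b.unit_vectors)

    def test_different_rng_seed_changes_jitter(self):
        a = sb.fibonacci_seeds(50, 0.2, rng_seed=0).unit_vectors
        b = sb.fibonacci_seeds(50, 0.2, rng_seed=1).unit_vectors
        assert not np.allclose(a, b)


# ---------------------------------------------------------------------------
# Delaunay triangulation (convex hull of the sphere)
# ---------------------------------------------------------------------------

class TestSphericalDelaunay:
    def test_tetrahedron_yields_four_triangles(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3)
        seeds = sb.SphericalSeedSet(pts, sb.SeedConfig(n_seeds=4))
        assert len(sb.spherical_delaunay(seeds)) == 4

    def test_euler_triangle_count(self):
        seeds = sb.fibonacci_seeds(50, 0.0)
        assert len(sb.spherical_delaunay(seeds)) == 2 * 50 - 4

    @pytest.mark.parametrize("n,seed", [(30, 0), (75, 5), (120, 9)])
    def test_every_seed_in_at_least_three_triangles(self, n, seed):
        seeds = sb.fibonacci_seeds(n, 0.15, rng_seed=seed)
        tri = sb.spherical_delaunay(seeds)
        counts = np.bincount(tri.ravel(), minlength=n)
        assert counts.min() >= 3

    def test_outward_orientation(self):
        seeds = sb.fibonacci_seeds(40, 0.1, rng_seed=2)
        tri = sb.spherical_delaunay(seeds)
        p = seeds.unit_vectors[tri]
        det = np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2]))
        assert np.all(det > 0)

    def test_degenerate_coplanar_seeds_rejected(self):
        pts = np.zeros((6, 3))
        theta = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts[:, 0], pts[:, 1] = np.cos(theta), np.sin(theta)
        seeds = sb.SphericalSeedSet(pts, sb.SeedConfig(n_seeds=6))
        with pytest.raises(TessellationDegeneracyError):
            sb.spherical_delaunay(seeds)


# ---------------------------------------------------------------------------
# Voronoi duality
# ---------------------------------------------------------------------------

class TestSphericalVoronoi:
    def test_tetrahedron_cells_cover_sphere_symmetrically(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3)
        seeds = sb.SphericalSeedSet(pts, sb.SeedConfig(n_seeds=4))
        tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
        sa = sb.solid_angles(tess)
        np.testing.assert_allclose(sa, np.pi, atol=1e-9)

    @pytest.mark.parametrize("n,jitter,seed", [(30, 0.1, 7), (100, 0.2, 1),
                                               (200, 0.0, 0)])
    def test_solid_angles_partition_sphere(self, n, jitter, seed):
        seeds = sb.fibonacci_seeds(n, jitter, rng_seed=seed)
        tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
        assert abs(sb.solid_angles(tess).sum() - 4 * np.pi) < 1e-9

    def test_voronoi_vertices_equidistant_from_generators(self):
        seeds = sb.fibonacci_seeds(30, 0.1, rng_seed=4)
        tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
        pts = seeds.unit_vectors
        for t, tri in enumerate(tess.delaunay_triangles):
            d = np.arccos(np.clip(pts[tri] @ tess.voronoi_vertices[t], -1, 1))
            assert d.max() - d.min() < 1e-9

    def test_duality_polygon_is_incident_triangle_set(self):
        seeds = sb.fibonacci_seeds(60, 0.15, rng_seed=3)
        tri = sb.spherical_delaunay(seeds)
        tess = sb.spherical_voronoi(seeds, tri)
        for s in range(seeds.n):
            incident = {t for t, tr in enumerate(tri) if s in tr}
            assert set(tess.voronoi_cells[s].tolist()) == incident

    def test_matches_scipy_spherical_voronoi_areas(self):
        # independent cross-check of the dual tessellation's cell areas
        from scipy.spatial import SphericalVoronoi
        seeds = sb.fibonacci_seeds(80, 0.1, rng_seed=11)
        tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
        sv = SphericalVoronoi(seeds.unit_vectors)
        sv.sort_vertices_of_regions()
        np.testing.assert_allclose(sb.solid_angles(tess),
                                   sv.calculate_areas(), atol=1e-9)


# ---------------------------------------------------------------------------
# extrusion into the 3D monolayer
# ---------------------------------------------------------------------------

class TestExtrudeShell:
    def test_thickness_by_construction(self, shell50):
        r = np.linalg.norm(shell50.vertices, axis=1)
        ap = r[shell50.vertex_layer == "apical"].mean()
        ba = r[shell50.vertex_layer == "basal"].mean()
        assert (ba - ap) / ba == pytest.approx(0.25, abs=1e-12)

    def test_tetrahedron_face_census(self):
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float) / np.sqrt(3)
        seeds = sb.SphericalSeedSet(pts, sb.SeedConfig(n_seeds=4))
        tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
        mesh = sb.extrude_shell(tess, 100.0, 0.25)
        assert mesh.n_cells == 4
        assert len(mesh.faces_of_type("apical")) == 4
        assert len(mesh.faces_of_type("basal")) == 4
        assert len(mesh.faces_of_type("lateral")) == 6

    def test_radii_exact_pre_relaxation(self, shell12):
        r = np.linalg.norm(shell12.vertices, axis=1)
        np.testing.assert_allclose(r[shell12.vertex_layer == "apical"], 80.0,
                                   atol=1e-9)
        np.testing.assert_allclose(r[shell12.vertex_layer == "basal"], 100.0,
                                   atol=1e-9)

    def test_invalid_thickness_rejected(self):
        seeds = sb.fibonacci_seeds(12, 0.0)
        tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
        for t in (0.0, 1.0, -0.5, 1.5):
            with pytest.raises(InvalidConfigurationError):
                sb.extrude_shell(tess, 100.0, t)

    def test_mesh_invariants_hold(self, shell50):
        sb.validate_mesh(shell50)

    def test_lateral_face_census_follows_euler(self, shell50):
        # n_lateral = number of Delaunay edges = 3 n - 6 on a closed sphere
        assert len(shell50.faces_of_type("lateral")) == 3 * 50 - 6

    def test_twelve_cell_lateral_degrees(self, shell12):
        degrees = [sum(1 for f in shell12.cells[c]
                       if shell12.face_type[f] == "lateral")
                   for c in range(12)]
        assert all(4 <= d <= 6 for d in degrees)
        assert sum(degrees) == 2 * (3 * 12 - 6)


class TestGenerateOrganoid:
    def test_cell_count_matches_seed_count(self):
        mesh = sb.generate_organoid(sb.SeedConfig(n_seeds=400))
        assert mesh.n_cells == 400

    def test_byte_identical_serialization_on_rerun(self):
        cfg = sb.SeedConfig(n_seeds=40, jitter_sigma=0.2, rng_seed=5)
        a = sb.generate_organoid(cfg).to_json()
        b = sb.generate_organoid(cfg).to_json()
        assert a == b

    def test_json_round_trip(self, shell12, tmp_path):
        p = tmp_path / "mesh.json"
        shell12.to_json(p)
        again = sb.OrganoidMesh.from_json(p)
        assert again.to_json() == shell12.to_json()

    def test_obj_and_vtk_exports_write(self, shell12, tmp_path):
        sb.write_obj(shell12, tmp_path / "m.obj")
        sb.write_vtk(shell12, tmp_path / "m.vtk")
        obj = (tmp_path / "m.obj").read_text()
        assert obj.count("o ") == 3 and "f " in obj
        vtk = (tmp_path / "m.vtk").read_text()
        assert "UNSTRUCTURED_GRID" in vtk and "face_type" in vtk


@settings(max_examples=15, deadline=None)
@given(n=st.integers(min_value=12, max_value=80),
       jitter=st.floats(min_value=0.0, max_value=0.3),
       seed=st.integers(min_value=0, max_value=1000))
def test_partition_property_any_configuration(n, jitter, seed):
    """Voronoi solid angles always partition the full sphere."""
    seeds = sb.fibonacci_seeds(n, jitter, rng_seed=seed)
    tess = sb.spherical_voronoi(seeds, sb.spherical_delaunay(seeds))
    assert abs(sb.solid_angles(tess).sum() - 4 * np.pi) < 1e-9
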