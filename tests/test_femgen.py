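"""Subcellular FEM discretization, materials and load plans."""

import numpy as np
import pytest

from organoidvm import avm, femgen
from organoidvm import shell_builder as sb
from organoidvm.errors import InvalidConfigurationError, MeshingError
from conftest import make_cube_cell


@pytest.fixture(scope="module")
def sub12(shell12):
    return femgen.assemble_submesh(shell12)


class TestTetrahedralization:
    def test_cube_cell_yields_24_tets_summing_to_one(self, cube_cell):
        sub = femgen.assemble_submesh(cube_cell)
        cyto = sub.blocks[femgen.BLOCK_CYTOPLASM]
        assert len(cyto) == 24   # 6 faces x 4 fan triangles
        p = sub.nodes[cyto.connectivity[:, :4]]
        v = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                      np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(1.0, rel=1e-12)

    def test_tet_count_equals_total_face_loop_length(self, shell12, sub12):
        expect = sum(len(shell12.faces[f]) for c in shell12.cells for f in c)
        assert len(sub12.blocks[femgen.BLOCK_CYTOPLASM]) == expect

    def test_degenerate_face_raises(self):
        mesh = make_cube_cell()
        mesh.vertices[5] = mesh.vertices[4]   # collapse one top edge
        with pytest.raises(MeshingError):
            femgen.assemble_submesh(mesh)

    def test_per_cell_volume_conservation(self, shell50):
        sub = femgen.assemble_submesh(shell50)
        femgen.validate_submesh(sub)   # includes the 1e-9 per-cell check


class TestQuadraticPromotion:
    def test_single_tet_has_ten_nodes(self):
        nodes = [np.array(p, dtype=float) for p in
                 [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        roles = ["cell-vertex"] * 4
        mid = {}
        out = femgen.promote_quadratic(np.array([[0, 1, 2, 3]]), nodes, roles, mid)
        assert out.shape == (1, 10)
        assert len(nodes) == 10

    def test_shared_face_midnodes_appear_once(self):
        nodes = [np.array(p, dtype=float) for p in
                 [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 1)]]
        roles = ["cell-vertex"] * 5
        mid = {}
        femgen.promote_quadratic(np.array([[0, 1, 2, 3], [1, 2, 3, 4]]),
                                 nodes, roles, mid)
        # 2 tets, 4 corners + shared face (1,2,3): unique edges = 9
        assert len(mid) == 9
        assert len(nodes) == 5 + 9

    def test_node_count_is_corners_plus_unique_edges(self, sub12):
        cyto = sub12.blocks[femgen.BLOCK_CYTOPLASM]
        corners = np.unique(cyto.connectivity[:, :4])
        edges = set()
        for tet in cyto.connectivity[:, :4]:
            for a in range(4):
                for b in range(a + 1, 4):
                    edges.add((min(tet[a], tet[b]), max(tet[a], tet[b])))
        mids = np.unique(cyto.connectivity[:, 4:])
        assert len(mids) == len(edges)
        assert len(corners) + len(mids) == len(np.unique(cyto.connectivity))

    def test_midpoints_exact(self, sub12):
        for (a, b), m in sub12.mid_edge.items():
            np.testing.assert_allclose(
                sub12.nodes[m], 0.5 * (sub12.nodes[a] + sub12.nodes[b]),
                atol=1e-12)


class TestMembranes:
    def test_cube_membrane_census(self, cube_cell):
        sub = femgen.assemble_submesh(cube_cell)
        assert len(sub.blocks[femgen.BLOCK_APICAL_MEMBRANE]) == 4
        assert len(sub.blocks[femgen.BLOCK_BASAL_MEMBRANE]) == 4
        assert len(sub.blocks[femgen.BLOCK_LATERAL_MEMBRANE]) == 16

    def test_membrane_nodes_subset_of_cytoplasm(self, sub12):
        cyto_nodes = set(np.unique(
            sub12.blocks[femgen.BLOCK_CYTOPLASM].connectivity))
        for name in (femgen.BLOCK_APICAL_MEMBRANE, femgen.BLOCK_BASAL_MEMBRANE,
                     femgen.BLOCK_LATERAL_MEMBRANE):
            mem_nodes = set(np.unique(sub12.blocks[name].connectivity))
            assert mem_nodes <= cyto_nodes

    def test_lateral_interfaces_emitted_once(self, shell12, sub12):
        # one 6-node triangle per lateral fan triangle, although each
        # lateral face is adjacent to two cells
        expect = sum(len(shell12.faces[f])
                     for f in shell12.faces_of_type("lateral"))
        assert len(sub12.blocks[femgen.BLOCK_LATERAL_MEMBRANE]) == expect

    def test_membranes_tile_cell_boundary_exactly_once(self, shell12, sub12):
        total = sum(len(sub12.blocks[n]) for n in (
            femgen.BLOCK_APICAL_MEMBRANE, femgen.BLOCK_BASAL_MEMBRANE,
            femgen.BLOCK_LATERAL_MEMBRANE))
        boundary_fans = sum(len(shell12.faces[f]) for f in range(shell12.n_faces))
        assert total == boundary_fans


class TestCortexRings:
    def test_ring_element_count_matches_polygon_edges(self, shell12, sub12):
        for ftype, name in femgen.CORTEX_BLOCK.items():
            expect = sum(len(shell12.faces[f])
                         for f in shell12.faces_of_type(ftype))
            assert len(sub12.blocks[name]) == expect

    def test_rings_close(self, shell12, sub12):
        blk = sub12.blocks[femgen.BLOCK_APICAL_CORTEX]
        f0 = shell12.faces_of_type("apical")[0]
        k = len(shell12.faces[f0])
        ring = blk.connectivity[:k]
        corners = [tuple(e[[0, 2]]) for e in ring]
        # consecutive elements chain and the last closes on the first
        for (a1, b1), (a2, b2) in zip(corners, corners[1:] + corners[:1]):
            assert b1 == a2

    def test_ring_lengths_sum_to_perimeter(self, shell12, sub12):
        blk = sub12.blocks[femgen.BLOCK_APICAL_CORTEX]
        f0 = shell12.faces_of_type("apical")[0]
        loop = shell12.faces[f0]
        perim = sum(np.linalg.norm(
            shell12.vertices[loop[i]] - shell12.vertices[loop[(i + 1) % len(loop)]])
            for i in range(len(loop)))
        k = len(loop)
        length = 0.0
        for e in blk.connectivity[:k]:
            length += np.linalg.norm(sub12.nodes[e[0]] - sub12.nodes[e[1]])
            length += np.linalg.norm(sub12.nodes[e[1]] - sub12.nodes[e[2]])
        assert length == pytest.approx(perim, abs=1e-12 * perim)


class TestLumen:
    def test_lumen_volume_conserved(self, shell12, sub12):
        lum = sub12.blocks[femgen.BLOCK_LUMEN]
        p = sub12.nodes[lum.connectivity]
        v = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                      np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
        assert np.all(v > 0)
        assert v.sum() == pytest.approx(avm.lumen_volume(shell12), rel=1e-9)

    def test_lumen_shares_apical_corner_nodes(self, sub12):
        lum_nodes = set(np.unique(sub12.blocks[femgen.BLOCK_LUMEN].connectivity))
        ap_nodes = set(np.unique(
            sub12.blocks[femgen.BLOCK_APICAL_MEMBRANE].connectivity[:, :3]))
        assert ap_nodes <= lum_nodes

    def test_standalone_mesh_lumen(self, shell12):
        pts, tets = femgen.mesh_lumen(shell12)
        p = pts[tets]
        v = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                      np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])).sum() / 6.0
        assert v == pytest.approx(avm.lumen_volume(shell12), rel=1e-9)


class TestAssembly:
    def test_eight_element_sets_match_material_names(self, sub12):
        mats = {m.name for m in femgen.default_materials()}
        assert set(sub12.blocks) == mats
        assert len(sub12.blocks) == 8

    def test_element_cell_map_covers_cell_elements(self, sub12):
        ecm = sub12.element_cell_map()
        for name, blk in sub12.blocks.items():
            for eid, cid in zip(blk.element_ids, blk.cell_ids):
                assert ecm[int(eid)] == int(cid)
            if name != femgen.BLOCK_LUMEN:
                assert (blk.cell_ids >= 0).all()

    def test_rerun_determinism(self, shell12):
        a = femgen.assemble_submesh(shell12)
        b = femgen.assemble_submesh(shell12)
        np.testing.assert_array_equal(a.nodes, b.nodes)
        for name in a.blocks:
            np.testing.assert_array_equal(a.blocks[name].connectivity,
                                          b.blocks[name].connectivity)

    def test_vtk_export_writes(self, sub12, tmp_path):
        femgen.write_submesh_vtk(sub12, tmp_path / "sub.vtk")
        text = (tmp_path / "sub.vtk").read_text()
        assert "UNSTRUCTURED_GRID" in text and "cell_id" in text


class TestMaterials:
    def test_default_library_values(self):
        mats = {m.name: m for m in femgen.default_materials()}
        assert mats["Cytoplasm"].poisson_ratio == 0.39
        assert mats["Cytoplasm"].young_modulus == pytest.approx(2.10e-3)
        assert mats["Basal membrane"].young_modulus == pytest.approx(2.00)
        assert mats["Lumen"].element_class == "C3D4"
        for m in mats.values():
            assert 0 < m.poisson_ratio < 0.5

    def test_invalid_material_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            femgen.MaterialSpec("x", "C3D4", -1.0, 0.3)
        with pytest.raises(InvalidConfigurationError):
            femgen.MaterialSpec("x", "C3D4", 1.0, 0.6)


class TestLoadPlans:
    def test_maturation_plan_steps_and_magnitudes(self):
        plan = femgen.plan_maturation()
        assert len(plan.steps) == 3
        s1 = {(ld.region, getattr(ld, "pascals", getattr(ld, "value", None)))
              for ld in plan.steps[0].loads}
        assert ("apical_surface", 90.0) in s1
        assert ("basal_surface", -500.0) in s1
        assert (femgen.BLOCK_LATERAL_CORTEX, -100.0) in s1
        s3 = {(ld.region, getattr(ld, "pascals", getattr(ld, "value", None)))
              for ld in plan.steps[2].loads}
        assert (femgen.BLOCK_BASAL_CORTEX, 400.0) in s3
        assert (femgen.BLOCK_APICAL_CORTEX, -300.0) in s3
        assert ("apical_surface", -1850.0) in s3
        assert ("basal_surface", -1210.0) in s3

    def test_swelling_plan_threefold(self):
        plan = femgen.plan_swelling(10.0, 20.0)
        assert plan.metadata["pressure_factor"] == 3.0
        step2 = {ld.region: ld.pascals for ld in plan.steps[1].loads}
        assert step2 == {"apical_surface": 30.0, "basal_surface": 60.0}

    def test_zero_base_pressures_warn(self):
        with pytest.warns(UserWarning):
            femgen.plan_swelling(0.0, 0.0)


class TestDisplacementField:
    def test_kernel_normalized_and_monotone(self):
        k = femgen.poisson_kernel(np.arange(10), 0.8)
        assert k[0] == pytest.approx(1.0)
        assert np.all(np.diff(k) < 0)

    def test_antipodal_magnitude_negligible(self, shell50):
        df = femgen.displacement_field(shell50, (0, 0, 1), 5.0)
        basal = np.flatnonzero(shell50.vertex_layer == "basal")
        dirs = shell50.vertices[basal]
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        bottom = int(basal[np.argmin(dirs @ np.array([0, 0, 1.0]))])
        assert np.linalg.norm(df[bottom]) < 0.01 * 5.0

    def test_all_displacements_point_inward(self, shell50):
        df = femgen.displacement_field(shell50, (1, 0, 0), 2.0)
        for v, u in df.items():
            assert np.dot(u, shell50.vertices[v]) <= 1e-12

    def test_negative_magnitude_rejected(self, shell50):
        with pytest.raises(InvalidConfigurationError):
            femgen.displacement_field(shell50, (0, 0, 1), -1.0)
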