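"""Subcellular finite-element discretization, material library and load plans.

Each vertex-model cell is decomposed into:

* cytoplasm — quadratic 10-node tetrahedra (one per face fan-triangle,
  connecting the cell centroid, the face centroid and two polygon vertices);
* membranes — quadratic 6-node triangles on the cell boundary, one per
  boundary fan-triangle, grouped apical/basal/lateral, reusing the cytoplasm
  nodes only (cell–cell interfaces are single, not duplicated, sheets);
* cortex — 3-node line elements (corner–midedge–corner) contouring each
  apical/basal/lateral polygon in a ring;
* lumen — linear 4-node tetrahedra fanning the apical surface from a lumen
  centroid node, corner nodes only.

Loads come in three families: surface pressures (Pa, positive = outward from
the cell), active contraction as a relative "temperature" in arbitrary units
driving thermal-expansion eigenstrain of the cortex, and prescribed nodal
displacements (external solicitation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

from . import avm
from .errors import InvalidConfigurationError, MeshingError, TopologyError
from .shell_builder import APICAL, BASAL, LATERAL, OrganoidMesh

ROLE_CELL_VERTEX = "cell-vertex"
ROLE_FACE_CENTROID = "face-centroid"
ROLE_CELL_CENTROID = "cell-centroid"
ROLE_MID_EDGE = "mid-edge"
ROLE_LUMEN_CENTROID = "lumen-centroid"

BLOCK_CYTOPLASM = "Cytoplasm"
BLOCK_APICAL_MEMBRANE = "Apical membrane"
BLOCK_BASAL_MEMBRANE = "Basal membrane"
BLOCK_LATERAL_MEMBRANE = "Lateral membrane"
BLOCK_APICAL_CORTEX = "Apical cortex"
BLOCK_BASAL_CORTEX = "Basal cortex"
BLOCK_LATERAL_CORTEX = "Lateral cortex"
BLOCK_LUMEN = "Lumen"

MEMBRANE_BLOCK = {APICAL: BLOCK_APICAL_MEMBRANE, BASAL: BLOCK_BASAL_MEMBRANE,
                  LATERAL: BLOCK_LATERAL_MEMBRANE}
CORTEX_BLOCK = {APICAL: BLOCK_APICAL_CORTEX, BASAL: BLOCK_BASAL_CORTEX,
                LATERAL: BLOCK_LATERAL_CORTEX}


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class ElementBlock:
    """Homogeneous element block: global ids, connectivity and cell map."""

    name: str
    elem_type: str                 # solver element code (C3D10M, STRI65, ...)
    element_ids: np.ndarray        # (n,) global ids
    connectivity: np.ndarray       # (n, k) node ids
    cell_ids: np.ndarray           # (n,) owning cell, -1 for the lumen

    def __len__(self) -> int:
        return len(self.element_ids)


@dataclass
class SubcellularMesh:
    """FEM discretization of an organoid mesh."""

    nodes: np.ndarray                      # (N, 3) μm
    node_role: np.ndarray                  # (N,) role strings
    blocks: dict[str, ElementBlock]
    surfaces: dict[str, np.ndarray]        # name -> (n, 3) corner triangles
    node_sets: dict[str, np.ndarray]
    source: OrganoidMesh | None = None
    mid_edge: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return sum(len(b) for b in self.blocks.values())

    def element_sets(self) -> dict[str, np.ndarray]:
        return {name: b.element_ids for name, b in self.blocks.items()}

    def element_cell_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for b in self.blocks.values():
            for eid, cid in zip(b.element_ids, b.cell_ids):
                out[int(eid)] = int(cid)
        return out


@dataclass
class MaterialSpec:
    """One row of the material library.

    Young's moduli are in MPa as printed; mass density is passed through as
    printed (quasi-static analyses make it inert).  The expansion coefficient
    is per arbitrary-unit relative temperature; viscous modulus and
    relaxation rate describe a single-term normalized shear-relaxation pair.
    """

    name: str
    element_class: str
    young_modulus: float          # MPa
    poisson_ratio: float
    mass_density: float | None = None
    expansion: float | None = None          # per a.u. temperature
    specific_heat: float | None = None      # a.u.
    viscous_modulus: float | None = None
    relaxation_rate: float | None = None

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise InvalidConfigurationError(f"{self.name}: young_modulus must be > 0")
        if not 0 < self.poisson_ratio < 0.5:
            raise InvalidConfigurationError(
                f"{self.name}: poisson_ratio must lie in (0, 0.5)")


def default_materials() -> list[MaterialSpec]:
    """The eight-material library of the organoid model (moduli in MPa)."""
    return [
        MaterialSpec(BLOCK_CYTOPLASM, "C3D10M", 2.10e-3, 0.39, 7.80e-9,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_APICAL_MEMBRANE, "STRI65", 1.00e-3, 0.35, 7.80e-9,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_BASAL_MEMBRANE, "STRI65", 2.00, 0.38, 7.80e-9,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_LATERAL_MEMBRANE, "STRI65", 1.00e-5, 0.42, 7.80e-9,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_APICAL_CORTEX, "T3D3T", 1.00e-3, 0.35, 7.80e-9,
                     expansion=3.00e-2, specific_heat=200,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_BASAL_CORTEX, "T3D3T", 2.00, 0.38, 7.80e-9,
                     expansion=1.50e-5, specific_heat=400,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_LATERAL_CORTEX, "T3D3T", 1.00e-4, 0.42, 7.80e-9,
                     expansion=6.00e-8, specific_heat=400,
                     viscous_modulus=0.01, relaxation_rate=0.3),
        MaterialSpec(BLOCK_LUMEN, "C3D4", 4.00e-6, 0.25, 1.00e-9),
    ]


# ---------------------------------------------------------------------------
# load plans
# ---------------------------------------------------------------------------

@dataclass
class SurfacePressure:
    """Uniform pressure on a named surface, Pa; positive = outward from cell."""

    region: str
    pascals: float
    kind: str = "surface_pressure"


@dataclass
class TemperatureLoad:
    """Relative temperature (a.u.) on a named cortex element set."""

    region: str
    value: float
    kind: str = "temperature_load"


@dataclass
class PrescribedDisplacement:
    """Per-node displacement vectors (μm) keyed by node id."""

    region: str
    displacements: dict[int, tuple[float, float, float]]
    kind: str = "prescribed_displacement"


Load = Union[SurfacePressure, TemperatureLoad, PrescribedDisplacement]


@dataclass
class LoadStep:
    name: str
    loads: list[Load]


@dataclass
class LoadPlan:
    """Ordered, cumulative solver steps (each starts from the previous state)."""

    steps: list[LoadStep]
    metadata: dict = field(default_factory=dict)

    def regions(self) -> set[str]:
        return {ld.region for st in self.steps for ld in st.loads}


def plan_maturation() -> LoadPlan:
    """Three-step immature → intermediate → mature loading sequence.

    Step 1 shapes the immature sphere (apical +90 Pa, basal −500 Pa) under
    lateral cortical contraction (−100 a.u.); step 2 relaxes the lateral
    cortex, expands apical/basal cortex (+100 a.u.) and deflates (−900 /
    −1000 Pa apical/basal); step 3 contracts the apical cortex (−300 a.u.),
    expands the basal (+400 a.u.) and lateral (+100 a.u.) cortex under
    −1850 / −1210 Pa apical/basal pressure.
    """
    return LoadPlan(steps=[
        LoadStep("immature", [
            SurfacePressure("apical_surface", 90.0),
            SurfacePressure("basal_surface", -500.0),
            TemperatureLoad(BLOCK_LATERAL_CORTEX, -100.0),
        ]),
        LoadStep("intermediate", [
            SurfacePressure("apical_surface", -900.0),
            SurfacePressure("basal_surface", -1000.0),
            TemperatureLoad(BLOCK_LATERAL_CORTEX, 0.0),
            TemperatureLoad(BLOCK_APICAL_CORTEX, 100.0),
            TemperatureLoad(BLOCK_BASAL_CORTEX, 100.0),
        ]),
        LoadStep("mature", [
            SurfacePressure("apical_surface", -1850.0),
            SurfacePressure("basal_surface", -1210.0),
            TemperatureLoad(BLOCK_APICAL_CORTEX, -300.0),
            TemperatureLoad(BLOCK_BASAL_CORTEX, 400.0),
            TemperatureLoad(BLOCK_LATERAL_CORTEX, 100.0),
        ]),
    ], metadata={"plan": "maturation"})


def plan_swelling(base_apical_pa: float, base_basal_pa: float,
                  factor: float = 3.0) -> LoadPlan:
    """Two-step osmotic swelling: step 2 scales both pressures by ``factor``."""
    if base_apical_pa == 0 and base_basal_pa == 0:
        warnings.warn("zero base pressures: the swelling plan is a no-op", stacklevel=2)
    return LoadPlan(steps=[
        LoadStep("control", [
            SurfacePressure("apical_surface", base_apical_pa),
            SurfacePressure("basal_surface", base_basal_pa),
        ]),
        LoadStep("swollen", [
            SurfacePressure("apical_surface", factor * base_apical_pa),
            SurfacePressure("basal_surface", factor * base_basal_pa),
        ]),
    ], metadata={"plan": "swelling", "pressure_factor": factor})


def poisson_kernel(rank: np.ndarray, rate: float) -> np.ndarray:
    """Poisson-pmf-shaped decay λ^k / k!, normalized to 1 at k = 0.

    Monotonically decaying for ``rate`` < 1.
    """
    from scipy.special import gammaln
    rank = np.asarray(rank, dtype=float)
    return np.exp(rank * np.log(rate) - gammaln(rank + 1.0))


def displacement_field(mesh: OrganoidMesh, pole_direction, u_max: float,
                       shape_param: float = 0.8, dist_scale: float | None = None,
                       kernel=poisson_kernel) -> dict[int, np.ndarray]:
    """Inward-radial displacement of basal-surface vertices around a pole.

    The magnitude is ``u_max * K(rank)`` where ``rank`` is the geodesic
    distance from the pole in units of ``dist_scale`` (default: mean basal
    radius × π/16), rounded to the nearest integer, and K is a normalized,
    monotonically decaying kernel (default Poisson-pmf-shaped with rate
    ``shape_param``).  The pole node moves by exactly ``u_max`` inward.
    """
    if u_max < 0:
        raise InvalidConfigurationError("u_max must be >= 0")
    if not 0 < shape_param < 1:
        raise InvalidConfigurationError(
            "shape_param must lie in (0, 1) for a monotonically decaying kernel")
    pole = np.asarray(pole_direction, dtype=float)
    pole /= np.linalg.norm(pole)
    center = mesh.vertices.mean(axis=0)
    basal = np.flatnonzero(mesh.vertex_layer == BASAL)
    pos = mesh.vertices[basal] - center
    radii = np.linalg.norm(pos, axis=1)
    dirs = pos / radii[:, None]
    if dist_scale is None:
        dist_scale = float(radii.mean()) * np.pi / 16.0
    geodesic = radii.mean() * np.arccos(np.clip(dirs @ pole, -1.0, 1.0))
    rank = np.round(geodesic / dist_scale)
    mag = u_max * kernel(rank, shape_param)
    return {int(v): -mag[i] * dirs[i] for i, v in enumerate(basal)}


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def _oriented_fan(mesh: OrganoidMesh, f: int, cell_id: int) -> list[tuple[int, int]]:
    """Perimeter vertex pairs (i, j) of face ``f`` such that the fan triangle
    (centroid, i, j) has its normal outward from ``cell_id``."""
    loop = mesh.faces[f]
    if mesh.face_normal_sign(f, cell_id) < 0:
        loop = loop[::-1]
    return [(int(loop[i]), int(loop[(i + 1) % len(loop)])) for i in range(len(loop))]


def tetrahedralize_cell(mesh: OrganoidMesh, cell_id: int,
                        face_centroid_node: dict[int, int],
                        cell_centroid_node: int,
                        nodes: np.ndarray) -> np.ndarray:
    """Linear tetrahedra of one cell: (face-centroid, v_j, v_i, cell-centroid).

    One tetra per face fan-triangle; all Jacobians positive; volumes sum to
    the cell's vertex-model volume exactly (identical fan decomposition).
    """
    tets = []
    cc = cell_centroid_node
    for f in mesh.cells[cell_id]:
        fc = face_centroid_node[int(f)]
        t = mesh.face_fan_triangles(f)
        areas = 0.5 * np.linalg.norm(
            np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
        if np.any(areas < 1e-12):
            raise MeshingError(f"cell {cell_id}, face {f}: degenerate fan triangle")
        # base triangle reversed so its normal faces the cell centroid
        for i, j in _oriented_fan(mesh, int(f), cell_id):
            tets.append((fc, j, i, cc))
    tets = np.asarray(tets, dtype=np.int64)
    p = nodes[tets]
    vol6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                     np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    if np.any(vol6 <= 0):
        bad = int(np.argmax(vol6 <= 0))
        raise MeshingError(f"cell {cell_id}: inverted tetrahedron at local index {bad}")
    return tets


def promote_quadratic(tets: np.ndarray, nodes: list[np.ndarray],
                      node_role: list[str],
                      mid_edge: dict[tuple[int, int], int]) -> np.ndarray:
    """Promote linear tetrahedra to 10-node by inserting shared mid-edge nodes.

    Node order per element: 4 corners, then midpoints of edges (1,2), (2,3),
    (3,1), (1,4), (2,4), (3,4).  Mid-edge nodes are shared across all
    incident elements (cytoplasm, membranes, cortex) via ``mid_edge``.
    """
    edge_order = [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)]
    out = np.empty((len(tets), 10), dtype=np.int64)
    out[:, :4] = tets
    for r, tet in enumerate(tets):
        for k, (a, b) in enumerate(edge_order):
            key = (int(min(tet[a], tet[b])), int(max(tet[a], tet[b])))
            nid = mid_edge.get(key)
            if nid is None:
                nid = len(nodes)
                nodes.append(0.5 * (np.asarray(nodes[key[0]]) + np.asarray(nodes[key[1]])))
                node_role.append(ROLE_MID_EDGE)
                mid_edge[key] = nid
            out[r, 4 + k] = nid
    return out


def mesh_lumen(mesh: OrganoidMesh) -> tuple[np.ndarray, np.ndarray]:
    """Standalone lumen tetrahedralization: (points, tets).

    One node per mesh vertex, one per apical face centroid, plus the lumen
    centroid last; one linear tetra per apical fan triangle, corner nodes
    only, all positively oriented, volumes summing to the lumen volume.
    """
    vol_check = avm.lumen_volume(mesh)   # raises TopologyError if open
    apical = mesh.faces_of_type(APICAL)
    points = [v for v in mesh.vertices]
    fc_node = {}
    for f in apical:
        fc_node[int(f)] = len(points)
        points.append(mesh.face_centroid(int(f)))
    corners = np.unique(np.concatenate([mesh.faces[f] for f in apical]))
    lc = len(points)
    points.append(mesh.vertices[corners].mean(axis=0))
    tets = []
    for f in apical:
        fc = fc_node[int(f)]
        loop = mesh.faces[f]
        for i in range(len(loop)):
            tets.append((fc, int(loop[i]), int(loop[(i + 1) % len(loop)]), lc))
    points = np.vstack(points)
    tets = np.asarray(tets, dtype=np.int64)
    p = points[tets]
    vol6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                     np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    if np.any(vol6 <= 0):
        raise MeshingError("inverted lumen tetrahedron")
    total = vol6.sum() / 6.0
    if abs(total - vol_check) > 1e-9 * vol_check:
        raise MeshingError("lumen tetrahedra do not reproduce the lumen volume")
    return points, tets


def assemble_submesh(mesh: OrganoidMesh) -> SubcellularMesh:
    """Build the full subcellular discretization of an organoid mesh.

    Deterministic numbering: vertex-model vertices first, then face
    centroids (face-id order), cell centroids (cell-id order), mid-edge
    nodes (creation order over cells by id), lumen centroid last.
    """
    nv = mesh.n_vertices
    node_list: list[np.ndarray] = [v for v in mesh.vertices]
    role_list: list[str] = [ROLE_CELL_VERTEX] * nv
    face_centroid_node: dict[int, int] = {}
    for f in range(mesh.n_faces):
        face_centroid_node[f] = len(node_list)
        node_list.append(mesh.face_centroid(f))
        role_list.append(ROLE_FACE_CENTROID)
    cell_centroid_node: dict[int, int] = {}
    for c in range(mesh.n_cells):
        cell_centroid_node[c] = len(node_list)
        node_list.append(mesh.cell_vertex_centroid(c))
        role_list.append(ROLE_CELL_CENTROID)

    nodes_arr = np.vstack(node_list)
    lin_tets = []
    tet_cells = []
    for c in range(mesh.n_cells):
        t = tetrahedralize_cell(mesh, c, face_centroid_node,
                                cell_centroid_node[c], nodes_arr)
        lin_tets.append(t)
        tet_cells.append(np.full(len(t), c, dtype=np.int64))
    lin_tets = np.vstack(lin_tets)
    tet_cells = np.concatenate(tet_cells)

    mid_edge: dict[tuple[int, int], int] = {}
    tet10 = promote_quadratic(lin_tets, node_list, role_list, mid_edge)

    # membranes: one 6-node triangle per boundary fan triangle, oriented
    # outward from the (lower-id) owner, reusing cytoplasm nodes only
    mem_conn: dict[str, list] = {APICAL: [], BASAL: [], LATERAL: []}
    mem_cells: dict[str, list] = {APICAL: [], BASAL: [], LATERAL: []}
    for f in range(mesh.n_faces):
        ftype = str(mesh.face_type[f])
        owner = mesh.face_cells[f][0]
        fc = face_centroid_node[f]
        for i, j in _oriented_fan(mesh, f, owner):
            tri = (fc, i, j)
            mids = []
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                key = (min(a, b), max(a, b))
                if key not in mid_edge:
                    raise MeshingError(
                        f"membrane triangle {tri} has no matching tetra face")
                mids.append(mid_edge[key])
            mem_conn[ftype].append(tri + tuple(mids))
            mem_cells[ftype].append(owner)

    # cortex rings: one corner–midedge–corner element per polygon perimeter edge
    cor_conn: dict[str, list] = {APICAL: [], BASAL: [], LATERAL: []}
    cor_cells: dict[str, list] = {APICAL: [], BASAL: [], LATERAL: []}
    for f in range(mesh.n_faces):
        ftype = str(mesh.face_type[f])
        owner = mesh.face_cells[f][0]
        loop = mesh.faces[f]
        for i in range(len(loop)):
            a, b = int(loop[i]), int(loop[(i + 1) % len(loop)])
            key = (min(a, b), max(a, b))
            cor_conn[ftype].append((a, mid_edge[key], b))
            cor_cells[ftype].append(owner)

    # lumen: fan of linear tets from the lumen centroid over the apical
    # surface; synthetic meshes whose apical faces do not close a surface
    # (no lumen to speak of) get an empty lumen block
    apical_fids = mesh.faces_of_type(APICAL)
    try:
        avm.lumen_volume(mesh)
        has_lumen = True
    except TopologyError:
        warnings.warn("apical surface is not closed; emitting an empty lumen "
                      "block", stacklevel=2)
        has_lumen = False
    lum_conn = []
    if has_lumen:
        apical_corner_nodes = np.unique(np.concatenate(
            [mesh.faces[f] for f in apical_fids]))
        lc = len(node_list)
        node_list.append(nodes_arr[apical_corner_nodes].mean(axis=0))
        role_list.append(ROLE_LUMEN_CENTROID)
        for f in apical_fids:
            fc = face_centroid_node[int(f)]
            loop = mesh.faces[f]
            # stored apical loops point toward the lumen: (fc, i, j) faces lc
            for i in range(len(loop)):
                lum_conn.append((fc, int(loop[i]),
                                 int(loop[(i + 1) % len(loop)]), lc))

    nodes = np.vstack(node_list)
    node_role = np.array(role_list)

    lum_conn = np.asarray(lum_conn, dtype=np.int64).reshape(-1, 4)
    if len(lum_conn):
        p = nodes[lum_conn]
        vol6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                         np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
        if np.any(vol6 <= 0):
            raise MeshingError(
                "inverted lumen tetrahedron (apical surface not star-shaped)")

    # global element numbering: cytoplasm, membranes, cortex, lumen
    blocks: dict[str, ElementBlock] = {}
    eid = 1

    def add_block(name: str, etype: str, conn, cells) -> None:
        nonlocal eid
        conn = np.asarray(conn, dtype=np.int64)
        blocks[name] = ElementBlock(
            name=name, elem_type=etype,
            element_ids=np.arange(eid, eid + len(conn), dtype=np.int64),
            connectivity=conn,
            cell_ids=np.asarray(cells, dtype=np.int64),
        )
        eid += len(conn)

    add_block(BLOCK_CYTOPLASM, "C3D10M", tet10, tet_cells)
    add_block(BLOCK_APICAL_MEMBRANE, "STRI65", mem_conn[APICAL], mem_cells[APICAL])
    add_block(BLOCK_BASAL_MEMBRANE, "STRI65", mem_conn[BASAL], mem_cells[BASAL])
    add_block(BLOCK_LATERAL_MEMBRANE, "STRI65", mem_conn[LATERAL], mem_cells[LATERAL])
    add_block(BLOCK_APICAL_CORTEX, "T3D3T", cor_conn[APICAL], cor_cells[APICAL])
    add_block(BLOCK_BASAL_CORTEX, "T3D3T", cor_conn[BASAL], cor_cells[BASAL])
    add_block(BLOCK_LATERAL_CORTEX, "T3D3T", cor_conn[LATERAL], cor_cells[LATERAL])
    add_block(BLOCK_LUMEN, "C3D4", lum_conn,
              np.full(len(lum_conn), -1, dtype=np.int64))

    surfaces = {
        "apical_surface": np.asarray([c[:3] for c in mem_conn[APICAL]], dtype=np.int64),
        "basal_surface": np.asarray([c[:3] for c in mem_conn[BASAL]], dtype=np.int64),
    }
    node_sets = {
        "apical_nodes": np.unique(surfaces["apical_surface"]),
        "basal_nodes": np.unique(surfaces["basal_surface"]),
    }
    for name, conn in ((BLOCK_APICAL_CORTEX, cor_conn[APICAL]),
                       (BLOCK_BASAL_CORTEX, cor_conn[BASAL]),
                       (BLOCK_LATERAL_CORTEX, cor_conn[LATERAL])):
        node_sets[name + " nodes"] = np.unique(np.asarray(conn, dtype=np.int64))

    return SubcellularMesh(nodes=nodes, node_role=node_role, blocks=blocks,
                           surfaces=surfaces, node_sets=node_sets,
                           source=mesh, mid_edge=mid_edge)


def validate_submesh(sub: SubcellularMesh) -> None:
    """Conformity checks: volume conservation, node subsets, single interfaces."""
    mesh = sub.source
    if mesh is None:
        raise TopologyError("submesh carries no source mesh")
    cyto = sub.blocks[BLOCK_CYTOPLASM]
    p = sub.nodes[cyto.connectivity[:, :4]]
    vols = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                     np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
    for c in range(mesh.n_cells):
        vfem = vols[cyto.cell_ids == c].sum()
        vvm = avm.cell_volume(mesh, c)
        if abs(vfem - vvm) > 1e-9 * vvm:
            raise TopologyError(f"cell {c}: FEM volume {vfem} != VM volume {vvm}")
    cyto_nodes = set(np.unique(cyto.connectivity))
    for name in (BLOCK_APICAL_MEMBRANE, BLOCK_BASAL_MEMBRANE, BLOCK_LATERAL_MEMBRANE,
                 BLOCK_APICAL_CORTEX, BLOCK_BASAL_CORTEX, BLOCK_LATERAL_CORTEX):
        extra = set(np.unique(sub.blocks[name].connectivity)) - cyto_nodes
        if extra:
            raise TopologyError(f"{name} has orphan nodes {sorted(extra)[:5]}")


# ---------------------------------------------------------------------------
# VTK export
# ---------------------------------------------------------------------------

_VTK_TYPE = {"C3D10M": 24, "STRI65": 22, "T3D3T": 21, "S3RT": 22, "C3D4": 10}


def write_submesh_vtk(sub: SubcellularMesh, path) -> None:
    """Legacy-VTK ASCII export with per-element material index and cell id."""
    mat_index = {name: i for i, name in enumerate(sub.blocks)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\norganoidvm submesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {sub.n_nodes} double\n")
        for v in sub.nodes:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        total = sum(len(b) * (b.connectivity.shape[1] + 1) for b in sub.blocks.values())
        fh.write(f"CELLS {sub.n_elements} {total}\n")
        for b in sub.blocks.values():
            for row in b.connectivity:
                fh.write(str(len(row)) + " " + " ".join(map(str, row)) + "\n")
        fh.write(f"CELL_TYPES {sub.n_elements}\n")
        for b in sub.blocks.values():
            code = _VTK_TYPE[b.elem_type]
            fh.write("\n".join([str(code)] * len(b)) + "\n")
        fh.write(f"CELL_DATA {sub.n_elements}\n")
        fh.write("SCALARS material int 1\nLOOKUP_TABLE default\n")
        for b in sub.blocks.values():
            fh.write("\n".join([str(mat_index[b.name])] * len(b)) + "\n")
        fh.write("SCALARS cell_id int 1\nLOOKUP_TABLE default\n")
        for b in sub.blocks.values():
            fh.write("\n".join(str(int(c)) for c in b.cell_ids) + "\n")
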