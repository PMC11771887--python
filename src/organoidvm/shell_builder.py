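"""Spherical monolayer shell generation.

An in-silico organoid starts as a closed single-cell-layer sphere.  The
construction runs in four deterministic steps:

1. seeds — a Fibonacci (golden-angle) lattice on the unit sphere, optionally
   perturbed by a tangent-plane Gaussian jitter;
2. Delaunay — the convex hull of the seeds triangulates the sphere;
3. Voronoi — the dual tessellation (normalized triangle circumcenters walked
   cyclically around each seed) delimits one polygonal territory per cell;
4. extrusion — the Voronoi shell is duplicated at two radii (apical inner,
   basal outer) and neighbouring cells are connected through lateral quads,
   producing a closed 3D monolayer of prism-like cells around a lumen.

Conventions used throughout the package:

* coordinates are right-handed Cartesian micrometres, organoid centroid at the
  origin;
* the thickness ratio is t = (R_basal - R_apical) / R_basal, with the basal
  (outer) surface at the measured organoid radius;
* every polygonal face is triangulated by a fan from its vertex centroid; all
  area/volume computations in the package share this convention;
* face loops are stored oriented so the outward normal points away from the
  owning cell's centroid (for lateral faces, away from the lower-id owner).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .errors import InvalidConfigurationError, TessellationDegeneracyError, TopologyError

APICAL = "apical"
BASAL = "basal"
LATERAL = "lateral"

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

# stage presets: measured relative shell thickness of immature / intermediate /
# mature organoids, and the mean stage radius (half the mean measured diameter)
STAGE_THICKNESS = {"immature": 0.07, "intermediate": 0.25, "mature": 0.4}
STAGE_RADIUS_UM = {"immature": 229.2, "intermediate": 114.2, "mature": 187.2}


# ---------------------------------------------------------------------------
# configuration and seed generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedConfig:
    """Parameters of the shell construction.

    Parameters
    ----------
    n_seeds
        Number of seeds, hence of cells (>= 4).  400 reproduces the default
        organoid-scale model.
    jitter_sigma
        Standard deviation of the tangent-plane Gaussian jitter, expressed as
        a fraction of the mean nearest-neighbour angular spacing of the
        jitter-free lattice.  0 keeps the exact Fibonacci lattice.
    rng_seed
        Seed of the pseudo-random generator; the whole construction is
        deterministic given the configuration.
    radius_basal
        Outer (basal) radius in micrometres.
    thickness_ratio
        Relative shell thickness t in (0, 1); the apical surface sits at
        radius_basal * (1 - t).
    """

    n_seeds: int = 400
    jitter_sigma: float = 0.2
    rng_seed: int = 0
    radius_basal: float = 175.0
    thickness_ratio: float = 0.25

    def __post_init__(self) -> None:
        if self.n_seeds < 4:
            raise InvalidConfigurationError(f"n_seeds must be >= 4, got {self.n_seeds}")
        if self.jitter_sigma < 0:
            raise InvalidConfigurationError("jitter_sigma must be >= 0")
        if not 0 < self.thickness_ratio < 1:
            raise InvalidConfigurationError(
                f"thickness_ratio must lie in (0, 1), got {self.thickness_ratio}"
            )
        if self.radius_basal <= 0:
            raise InvalidConfigurationError("radius_basal must be positive")


@dataclass(frozen=True)
class SphericalSeedSet:
    """Unit vectors of the cell seeds plus the configuration they came from."""

    unit_vectors: np.ndarray  # (n, 3), each of norm 1
    provenance: SeedConfig

    @property
    def n(self) -> int:
        return len(self.unit_vectors)


def _fibonacci_lattice(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def mean_nn_angular_spacing(points: np.ndarray) -> float:
    """Mean angular distance (radians) from each point to its nearest neighbour."""
    d, _ = cKDTree(points).query(points, k=2)
    chord = d[:, 1]
    return float(np.mean(2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))))


def fibonacci_seeds(n: int, jitter_sigma: float = 0.0, rng_seed: int = 0,
                    config: SeedConfig | None = None) -> SphericalSeedSet:
    """Distribute ``n`` seeds on the unit sphere with a golden-angle lattice.

    With ``jitter_sigma > 0`` every point is displaced in its tangent plane by
    a zero-mean isotropic Gaussian whose standard deviation is
    ``jitter_sigma`` times the mean nearest-neighbour angular spacing of the
    jitter-free lattice, then renormalized onto the sphere.
    """
    if config is None:
        config = SeedConfig(n_seeds=n, jitter_sigma=jitter_sigma, rng_seed=rng_seed)
    if n < 4:
        raise InvalidConfigurationError(f"need at least 4 seeds, got {n}")
    pts = _fibonacci_lattice(n)
    if jitter_sigma > 0:
        sigma = jitter_sigma * mean_nn_angular_spacing(pts)
        rng = np.random.default_rng(rng_seed)
        # orthonormal tangent frame at each point
        ref = np.zeros_like(pts)
        ref[:, 0] = 1.0
        ref[np.abs(pts[:, 0]) > 0.9, 0] = 0.0
        ref[np.abs(pts[:, 0]) > 0.9, 1] = 1.0
        e1 = np.cross(pts, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(pts, e1)
        g = rng.standard_normal((n, 2)) * sigma
        pts = pts + g[:, :1] * e1 + g[:, 1:] * e2
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    # pairwise distinctness (cheap check via nearest neighbour)
    d, _ = cKDTree(pts).query(pts, k=2)
    if np.min(d[:, 1]) < 1e-12:
        raise TessellationDegeneracyError("coincident seeds after jitter; change rng_seed")
    return SphericalSeedSet(unit_vectors=pts, provenance=config)


# ---------------------------------------------------------------------------
# tessellation
# ---------------------------------------------------------------------------

@dataclass
class ShellTessellation:
    """Dual Delaunay/Voronoi tessellation of the seeded sphere.

    ``voronoi_vertices[i]`` is the unit-normalized circumcenter of Delaunay
    triangle ``delaunay_triangles[i]``; ``voronoi_cells[s]`` lists the
    triangle/vertex indices bounding seed ``s``'s polygon in counterclockwise
    order as seen from outside the sphere.
    """

    seeds: SphericalSeedSet
    delaunay_triangles: np.ndarray          # (T, 3) seed indices, outward ccw
    voronoi_vertices: np.ndarray            # (T, 3) unit vectors
    voronoi_cells: list[np.ndarray]         # per seed: ordered voronoi vertex ids
    adjacency: list[np.ndarray] = field(default_factory=list)  # per seed: neighbour seeds

    @property
    def n_cells(self) -> int:
        return self.seeds.n


def spherical_delaunay(seeds: SphericalSeedSet) -> np.ndarray:
    """Delaunay triangulation of the sphere = convex hull of the seed points.

    Returns (T, 3) seed-index triples with consistent outward (counter-
    clockwise from outside) orientation.
    """
    pts = seeds.unit_vectors
    if len(pts) < 4:
        raise TessellationDegeneracyError("need at least 4 seeds")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # coplanar / degenerate input
        raise TessellationDegeneracyError(f"degenerate seed set: {exc}") from exc
    if len(hull.vertices) != len(pts):
        missing = sorted(set(range(len(pts))) - set(hull.vertices))
        raise TessellationDegeneracyError(
            f"seeds {missing} are not hull vertices (degenerate configuration)"
        )
    tri = hull.simplices.copy()
    # orient outward: the sphere is centred at the origin, so the signed
    # triple product of the triangle vertices must be positive
    det = np.einsum("ij,ij->i", pts[tri[:, 0]], np.cross(pts[tri[:, 1]], pts[tri[:, 2]]))
    flip = det < 0
    tri[flip] = tri[flip][:, [0, 2, 1]]
    return tri


def spherical_voronoi(seeds: SphericalSeedSet, triangles: np.ndarray) -> ShellTessellation:
    """Dual Voronoi tessellation: circumcenters walked cyclically per seed."""
    pts = seeds.unit_vectors
    a, b, c = pts[triangles[:, 0]], pts[triangles[:, 1]], pts[triangles[:, 2]]
    cc = np.cross(b - a, c - a)
    norms = np.linalg.norm(cc, axis=1)
    if np.any(norms < 1e-14):
        bad = int(np.argmin(norms))
        raise TessellationDegeneracyError(f"triangle {bad} {triangles[bad]} is degenerate")
    cc /= norms[:, None]
    # circumradius check: the circumcenter must stay within a quarter sphere
    # of its generators, else the dual polygon is ill-defined
    cosr = np.einsum("ij,ij->i", cc, a)
    if np.any(cosr <= 1e-9):
        bad = int(np.argmin(cosr))
        raise TessellationDegeneracyError(
            f"triangle {bad} {triangles[bad]} has circumradius >= pi/2 on the sphere"
        )

    n = seeds.n
    # successor map around each seed: in triangle (s, p, q) (cyclic), q follows p
    succ: list[dict[int, tuple[int, int]]] = [dict() for _ in range(n)]
    for t, (i, j, k) in enumerate(triangles):
        succ[i][j] = (k, t)
        succ[j][k] = (i, t)
        succ[k][i] = (j, t)

    cells: list[np.ndarray] = []
    adjacency: list[np.ndarray] = []
    for s in range(n):
        ring = succ[s]
        if len(ring) < 3:
            raise TessellationDegeneracyError(
                f"seed {s} has a degenerate Voronoi polygon ({len(ring)} vertices); "
                "reduce jitter_sigma or change rng_seed"
            )
        start = next(iter(ring))
        order_tris: list[int] = []
        order_nbrs: list[int] = []
        p = start
        for _ in range(len(ring)):
            q, t = ring[p]
            order_tris.append(t)
            order_nbrs.append(p)
            p = q
        if p != start:
            raise TessellationDegeneracyError(
                f"triangle fan around seed {s} does not close (non-manifold hull)"
            )
        cells.append(np.array(order_tris, dtype=np.int64))
        adjacency.append(np.array(order_nbrs, dtype=np.int64))

    return ShellTessellation(
        seeds=seeds,
        delaunay_triangles=np.asarray(triangles, dtype=np.int64),
        voronoi_vertices=cc,
        voronoi_cells=cells,
        adjacency=adjacency,
    )


def solid_angles(tess: ShellTessellation) -> np.ndarray:
    """Solid angle of each Voronoi cell (Van Oosterom–Strackee fan from the seed)."""
    out = np.empty(tess.n_cells)
    V = tess.voronoi_vertices
    for s, loop in enumerate(tess.voronoi_cells):
        o = tess.seeds.unit_vectors[s]
        v1 = V[loop]
        v2 = V[np.roll(loop, -1)]
        num = np.einsum("ij,j->i", np.cross(v1, v2), o)
        den = 1.0 + v1 @ o + v2 @ o + np.einsum("ij,ij->i", v1, v2)
        out[s] = float(np.sum(2.0 * np.arctan2(num, den)))
    return out


# ---------------------------------------------------------------------------
# the organoid mesh
# ---------------------------------------------------------------------------

@dataclass
class OrganoidMesh:
    """Shared-vertex polygonal cell complex of a closed monolayer shell.

    Vertices come in two concentric layers (apical inner / basal outer); each
    cell is bounded by one apical polygon, one basal polygon and one lateral
    quad per neighbour.  Lateral faces are single shared interfaces between
    the two adjacent cells.
    """

    vertices: np.ndarray            # (Nv, 3) μm
    vertex_layer: np.ndarray        # (Nv,) "apical" | "basal"
    faces: list[np.ndarray]         # ordered vertex loops
    face_type: np.ndarray           # (F,) "apical" | "basal" | "lateral"
    face_cells: list[tuple[int, ...]]  # owner cell ids (1 or 2)
    cells: list[np.ndarray]         # per cell: face ids
    cell_seed: np.ndarray           # (C,) originating seed index
    seed_directions: np.ndarray     # (C, 3) unit vectors
    lumen_point: np.ndarray         # shell centroid, μm
    radius_basal: float | None = None
    thickness_ratio: float | None = None

    # -- basic census ------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def faces_of_type(self, ftype: str) -> np.ndarray:
        return np.flatnonzero(self.face_type == ftype)

    # -- geometry helpers (fan-from-centroid convention) -------------------
    def face_centroid(self, f: int) -> np.ndarray:
        return self.vertices[self.faces[f]].mean(axis=0)

    def face_fan_triangles(self, f: int) -> np.ndarray:
        """(k, 3, 3) triangle coordinates (centroid, v_i, v_{i+1})."""
        loop = self.faces[f]
        p = self.vertices[loop]
        c = p.mean(axis=0)
        k = len(loop)
        tris = np.empty((k, 3, 3))
        tris[:, 0] = c
        tris[:, 1] = p
        tris[:, 2] = p[np.roll(np.arange(k), -1)]
        return tris

    def face_area(self, f: int) -> float:
        t = self.face_fan_triangles(f)
        n = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return float(0.5 * np.linalg.norm(n, axis=1).sum())

    def face_normal_sign(self, f: int, cell_id: int) -> float:
        """+1 if the stored loop is oriented outward from ``cell_id``."""
        owners = self.face_cells[f]
        if cell_id not in owners:
            raise TopologyError(f"cell {cell_id} does not own face {f}")
        return 1.0 if cell_id == owners[0] else -1.0

    def cell_vertex_ids(self, cell_id: int) -> np.ndarray:
        vs = np.concatenate([self.faces[f] for f in self.cells[cell_id]])
        return np.unique(vs)

    def cell_vertex_centroid(self, cell_id: int) -> np.ndarray:
        return self.vertices[self.cell_vertex_ids(cell_id)].mean(axis=0)

    def cell_edges(self, cell_id: int) -> dict[tuple[int, int], int]:
        """Undirected edge -> number of cell faces containing it."""
        count: dict[tuple[int, int], int] = {}
        for f in self.cells[cell_id]:
            loop = self.faces[f]
            for i in range(len(loop)):
                e = (int(loop[i]), int(loop[(i + 1) % len(loop)]))
                e = (min(e), max(e))
                count[e] = count.get(e, 0) + 1
        return count

    def unique_edges(self) -> np.ndarray:
        """(E, 2) sorted unique geometric edges over all faces."""
        pairs = []
        for loop in self.faces:
            nxt = np.roll(loop, -1)
            pairs.append(np.sort(np.column_stack([loop, nxt]), axis=1))
        allp = np.vstack(pairs)
        return np.unique(allp, axis=0)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "format": "organoidvm-mesh",
            "version": 1,
            "units": "um",
            "vertices": self.vertices.tolist(),
            "vertex_layer": self.vertex_layer.tolist(),
            "faces": [f.tolist() for f in self.faces],
            "face_type": self.face_type.tolist(),
            "face_cells": [list(fc) for fc in self.face_cells],
            "cells": [c.tolist() for c in self.cells],
            "cell_seed": self.cell_seed.tolist(),
            "seed_directions": self.seed_directions.tolist(),
            "lumen_point": self.lumen_point.tolist(),
            "radius_basal": self.radius_basal,
            "thickness_ratio": self.thickness_ratio,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict())
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "OrganoidMesh":
        if d.get("format") != "organoidvm-mesh":
            raise InvalidConfigurationError("not an organoidvm mesh document")
        return cls(
            vertices=np.asarray(d["vertices"], dtype=float),
            vertex_layer=np.asarray(d["vertex_layer"]),
            faces=[np.asarray(f, dtype=np.int64) for f in d["faces"]],
            face_type=np.asarray(d["face_type"]),
            face_cells=[tuple(fc) for fc in d["face_cells"]],
            cells=[np.asarray(c, dtype=np.int64) for c in d["cells"]],
            cell_seed=np.asarray(d["cell_seed"], dtype=np.int64),
            seed_directions=np.asarray(d["seed_directions"], dtype=float),
            lumen_point=np.asarray(d["lumen_point"], dtype=float),
            radius_basal=d.get("radius_basal"),
            thickness_ratio=d.get("thickness_ratio"),
        )

    @classmethod
    def from_json(cls, source) -> "OrganoidMesh":
        if hasattr(source, "read"):
            text = source.read()
        else:
            try:
                with open(source) as fh:
                    text = fh.read()
            except (OSError, ValueError):
                text = source
        return cls.from_dict(json.loads(text))


def extrude_shell(tess: ShellTessellation, radius_basal: float,
                  thickness_ratio: float) -> OrganoidMesh:
    """Extrude the spherical Voronoi tessellation into a closed 3D monolayer.

    Each Voronoi polygon becomes one prism-like cell with an apical copy at
    radius ``radius_basal * (1 - thickness_ratio)``, a basal copy at
    ``radius_basal`` and one lateral quad per Voronoi edge, shared between the
    two adjacent cells.
    """
    if not 0 < thickness_ratio < 1:
        raise InvalidConfigurationError("thickness_ratio must lie in (0, 1)")
    if radius_basal <= 0:
        raise InvalidConfigurationError("radius_basal must be positive")
    nv = len(tess.voronoi_vertices)
    r_ap = radius_basal * (1.0 - thickness_ratio)
    vertices = np.vstack([tess.voronoi_vertices * r_ap,
                          tess.voronoi_vertices * radius_basal])
    vertex_layer = np.array([APICAL] * nv + [BASAL] * nv)

    n_cells = tess.n_cells
    faces: list[np.ndarray] = []
    face_type: list[str] = []
    face_cells: list[tuple[int, ...]] = []
    cell_faces: list[list[int]] = [[] for _ in range(n_cells)]

    # apical faces: Voronoi loop is ccw viewed from outside; outward from the
    # cell means pointing toward the lumen, i.e. the reversed loop
    for s in range(n_cells):
        loop = tess.voronoi_cells[s]
        faces.append(loop[::-1].copy())
        face_type.append(APICAL)
        face_cells.append((s,))
        cell_faces[s].append(len(faces) - 1)
    # basal faces keep the ccw loop (outward normal = radially out)
    for s in range(n_cells):
        loop = tess.voronoi_cells[s]
        faces.append(loop + nv)
        face_type.append(BASAL)
        face_cells.append((s,))
        cell_faces[s].append(len(faces) - 1)

    # lateral faces: one quad per Voronoi edge, shared by the two seeds whose
    # territories border it
    edge_owners: dict[tuple[int, int], list[int]] = {}
    for s in range(n_cells):
        loop = tess.voronoi_cells[s]
        for i in range(len(loop)):
            e = (int(loop[i]), int(loop[(i + 1) % len(loop)]))
            key = (min(e), max(e))
            edge_owners.setdefault(key, []).append(s)
    seeds = tess.seeds.unit_vectors
    for key in sorted(edge_owners):
        owners = sorted(edge_owners[key])
        if len(owners) != 2:
            raise TopologyError(f"Voronoi edge {key} owned by {len(owners)} cells")
        c1, c2 = owners
        t1, t2 = key
        quad = np.array([t1, t2, t2 + nv, t1 + nv], dtype=np.int64)
        # orient away from the lower-id owner c1
        p = vertices[quad]
        normal = np.cross(p[1] - p[0], p[2] - p[0]) + np.cross(p[2] - p[0], p[3] - p[0])
        if float(normal @ (seeds[c2] - seeds[c1])) < 0:
            quad = quad[::-1].copy()
        faces.append(quad)
        face_type.append(LATERAL)
        face_cells.append((c1, c2))
        cell_faces[c1].append(len(faces) - 1)
        cell_faces[c2].append(len(faces) - 1)

    mesh = OrganoidMesh(
        vertices=vertices,
        vertex_layer=vertex_layer,
        faces=faces,
        face_type=np.array(face_type),
        face_cells=face_cells,
        cells=[np.array(cf, dtype=np.int64) for cf in cell_faces],
        cell_seed=np.arange(n_cells, dtype=np.int64),
        seed_directions=seeds.copy(),
        lumen_point=vertices.mean(axis=0),
        radius_basal=float(radius_basal),
        thickness_ratio=float(thickness_ratio),
    )
    return mesh


def generate_organoid(config: SeedConfig) -> OrganoidMesh:
    """Run the four-step construction for one configuration (deterministic)."""
    seeds = fibonacci_seeds(config.n_seeds, config.jitter_sigma, config.rng_seed,
                            config=config)
    tri = spherical_delaunay(seeds)
    tess = spherical_voronoi(seeds, tri)
    return extrude_shell(tess, config.radius_basal, config.thickness_ratio)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_mesh(mesh: OrganoidMesh) -> None:
    """Check the structural invariants of an OrganoidMesh; raise TopologyError."""
    for f, (ftype, owners) in enumerate(zip(mesh.face_type, mesh.face_cells)):
        want = 2 if ftype == LATERAL else 1
        if len(owners) != want:
            raise TopologyError(f"face {f} ({ftype}) has {len(owners)} owners, expected {want}")
    for c in range(mesh.n_cells):
        for e, cnt in mesh.cell_edges(c).items():
            if cnt != 2:
                raise TopologyError(f"cell {c}: edge {e} lies in {cnt} faces, expected 2")
    for ftype in (APICAL, BASAL):
        fids = mesh.faces_of_type(ftype)
        verts = set()
        edges = set()
        for f in fids:
            loop = mesh.faces[f]
            verts.update(int(v) for v in loop)
            for i in range(len(loop)):
                e = (int(loop[i]), int(loop[(i + 1) % len(loop)]))
                edges.add((min(e), max(e)))
        euler = len(verts) - len(edges) + len(fids)
        if euler != 2:
            raise TopologyError(f"{ftype} surface has Euler characteristic {euler}, expected 2")


# ---------------------------------------------------------------------------
# exports (OBJ and legacy-VTK ASCII are tiny text formats, written directly)
# ---------------------------------------------------------------------------

def write_obj(mesh: OrganoidMesh, path) -> None:
    """Export the polygonal surfaces as OBJ with one group per face type."""
    with open(path, "w") as fh:
        fh.write("# organoidvm surface export\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for ftype in (APICAL, BASAL, LATERAL):
            fh.write(f"o {ftype}\n")
            for f in mesh.faces_of_type(ftype):
                loop = " ".join(str(int(v) + 1) for v in mesh.faces[f])
                fh.write(f"f {loop}\n")


def write_vtk(mesh: OrganoidMesh, path) -> None:
    """Export as a legacy-VTK ASCII unstructured grid of polygons."""
    type_code = {APICAL: 0, BASAL: 1, LATERAL: 2}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\norganoidvm mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        total = sum(len(f) + 1 for f in mesh.faces)
        fh.write(f"CELLS {mesh.n_faces} {total}\n")
        for loop in mesh.faces:
            fh.write(str(len(loop)) + " " + " ".join(str(int(v)) for v in loop) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_faces}\n")
        fh.write("\n".join(["7"] * mesh.n_faces) + "\n")  # VTK_POLYGON
        fh.write(f"CELL_DATA {mesh.n_faces}\n")
        fh.write("SCALARS face_type int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(type_code[t]) for t in mesh.face_type) + "\n")
        fh.write("SCALARS owner_cell int 1\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(fc[0]) for fc in mesh.face_cells) + "\n")
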