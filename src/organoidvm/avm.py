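"""Active vertex model: energy, analytic gradient and quasi-static relaxation.

The monolayer's mechanical state is scored by the energy

    E = Λ Σ_e l_e  +  T_f Σ_f A_f
        + Σ_c [ K_A/2 (A_c − A_c0)² + K_V/2 (V_c − V_c0)² ]
        + K_lum/2 (V_lum − V_lum0)²

where l_e are geometric edge lengths, A_f geometric face areas (each edge and
face counted once), A_c and V_c each cell's total surface area and volume
(shared faces counted fully for every owner), and V_lum the lumen volume
enclosed by the apical surface.  The subscript 0 marks the reference state,
captured from the initial mesh by default.

Equilibrium is found by quasi-Newton (L-BFGS-B) minimization over all vertex
coordinates with the analytic gradient below; the connectivity never changes.

Units: lengths μm, areas μm², volumes μm³, energies fJ.  Coefficients follow
the model's parameter table: Λ in fJ/μm, T_f in fJ/μm², K_A in fJ/μm⁴, K_V
and K_lum in fJ/μm⁹ (as printed).  The tabulated "contractility" (nN·μm) has
no term in the energy above; it is stored and reported for completeness but
not evaluated.

Geometric note: every polygonal face is fan-triangulated from its vertex
centroid.  The fan closure makes each cell boundary (and the apical surface)
a closed oriented triangulated surface for *any* vertex positions, so signed
volumes are computed from the origin; the value is identical to the
tetrahedra-from-cell-centroid definition and reference-point independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize
import scipy.sparse as sp

from .errors import InvalidConfigurationError, TopologyError
from .shell_builder import APICAL, OrganoidMesh


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass
class ReferenceState:
    """Per-cell reference areas/volumes and the reference lumen volume."""

    cell_area: np.ndarray    # (C,) μm²
    cell_volume: np.ndarray  # (C,) μm³
    lumen_volume: float      # μm³


@dataclass
class AVMParameters:
    """Coefficients of the vertex energy (defaults follow the model's table).

    ``lumen_elasticity`` defaults to 0.001 × cell count and is resolved when
    the energy is evaluated.  ``contractility`` is stored but has no
    corresponding energy term.
    """

    line_tension: float = 50.0          # Λ, fJ/μm
    surface_tension: float = 10.0       # T_f, fJ/μm²
    contractility: float = 0.1          # nN·μm (stored only)
    area_elasticity: float = 1000.0     # K_A, fJ/μm⁴
    volume_elasticity: float = 1000.0   # K_V, fJ/μm⁹
    lumen_elasticity: float | None = None  # K_lum, fJ/μm⁹; None -> 0.001 × n_cells
    reference_state: ReferenceState | None = None

    def __post_init__(self) -> None:
        for name in ("line_tension", "surface_tension", "area_elasticity",
                     "volume_elasticity"):
            if getattr(self, name) < 0:
                raise InvalidConfigurationError(f"{name} must be >= 0")
        if self.lumen_elasticity is not None and self.lumen_elasticity < 0:
            raise InvalidConfigurationError("lumen_elasticity must be >= 0")

    def resolved_lumen_elasticity(self, n_cells: int) -> float:
        if self.lumen_elasticity is None:
            return 0.001 * n_cells
        return self.lumen_elasticity

    def with_reference(self, mesh: OrganoidMesh) -> "AVMParameters":
        """Return a copy whose reference state is captured from ``mesh``.

        On synthetic meshes whose apical faces do not close a surface the
        lumen reference falls back to the raw signed apical flux, matching
        how the energy evaluates it, so the lumen term still starts at zero.
        """
        try:
            lum = lumen_volume(mesh)
        except TopologyError:
            lum = _lumen_signed(mesh)
        ref = ReferenceState(
            cell_area=np.array([cell_area(mesh, c) for c in range(mesh.n_cells)]),
            cell_volume=np.array([cell_volume(mesh, c) for c in range(mesh.n_cells)]),
            lumen_volume=lum,
        )
        return replace(self, reference_state=ref)


@dataclass
class EnergyBreakdown:
    """Per-term decomposition of the vertex energy (all fJ)."""

    edge_term: float
    face_term: float
    area_term: float
    volume_term: float
    lumen_term: float

    @property
    def total(self) -> float:
        return (self.edge_term + self.face_term + self.area_term
                + self.volume_term + self.lumen_term)


@dataclass
class RelaxationTrace:
    """Per-iteration record of an energy minimization."""

    energy: list[float] = field(default_factory=list)      # fJ
    grad_norm: list[float] = field(default_factory=list)   # fJ/μm (max component)
    termination: str = ""
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# topology cache (connectivity is fixed during relaxation)
# ---------------------------------------------------------------------------

class _Topology:
    """Flat index arrays describing a mesh's connectivity, built once."""

    def __init__(self, mesh: OrganoidMesh):
        self.n_vertices = mesh.n_vertices
        self.n_faces = mesh.n_faces
        self.n_cells = mesh.n_cells
        self.edges = mesh.unique_edges()

        tri_face, tri_a, tri_b = [], [], []
        rows, cols, vals = [], [], []
        for f, loop in enumerate(mesh.faces):
            k = len(loop)
            nxt = np.roll(loop, -1)
            tri_face.append(np.full(k, f))
            tri_a.append(loop)
            tri_b.append(nxt)
            rows.append(np.full(k, f))
            cols.append(loop)
            vals.append(np.full(k, 1.0 / k))
        self.tri_face = np.concatenate(tri_face)
        self.tri_a = np.concatenate(tri_a).astype(np.int64)
        self.tri_b = np.concatenate(tri_b).astype(np.int64)
        self.centroid_op = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_faces, self.n_vertices),
        )
        # (cell, face) incidence with orientation sign (+1 if the stored loop
        # is outward from that cell)
        inc_cell, inc_face, inc_sign = [], [], []
        for c, fids in enumerate(mesh.cells):
            for f in fids:
                inc_cell.append(c)
                inc_face.append(int(f))
                inc_sign.append(1.0 if mesh.face_cells[f][0] == c else -1.0)
        self.inc = sp.csr_matrix(
            (np.ones(len(inc_cell)), (inc_cell, inc_face)),
            shape=(self.n_cells, self.n_faces),
        )
        self.inc_signed = sp.csr_matrix(
            (np.array(inc_sign), (inc_cell, inc_face)),
            shape=(self.n_cells, self.n_faces),
        )
        # apical faces are stored oriented toward the lumen; outward from the
        # lumen is the opposite orientation, hence the −1 weight
        self.lumen_sign = np.where(mesh.face_type == APICAL, -1.0, 0.0)


def _geometry(topo: _Topology, X: np.ndarray):
    """Face areas, face signed volumes (from origin) and triangle intermediates."""
    cent = topo.centroid_op @ X
    A = X[topo.tri_a]
    B = X[topo.tri_b]
    Cf = cent[topo.tri_face]
    u = A - Cf
    w = B - Cf
    n = np.cross(u, w)
    nrm = np.linalg.norm(n, axis=1)
    tri_area = 0.5 * nrm
    face_area = np.bincount(topo.tri_face, tri_area, minlength=topo.n_faces)
    tri_vol6 = np.einsum("ij,ij->i", Cf, np.cross(A, B))
    face_vol = np.bincount(topo.tri_face, tri_vol6, minlength=topo.n_faces) / 6.0
    return cent, A, B, Cf, u, w, n, nrm, face_area, face_vol


# ---------------------------------------------------------------------------
# elementary measures
# ---------------------------------------------------------------------------

def _check_cell_closed(mesh: OrganoidMesh, cell_id: int) -> None:
    for e, cnt in mesh.cell_edges(cell_id).items():
        if cnt != 2:
            raise TopologyError(
                f"cell {cell_id} is not edge-closed: edge {e} lies in {cnt} faces"
            )


def cell_volume(mesh: OrganoidMesh, cell_id: int) -> float:
    """Volume of one cell (μm³) by fan tetrahedra from its vertex centroid."""
    _check_cell_closed(mesh, cell_id)
    b = mesh.cell_vertex_centroid(cell_id)
    vol = 0.0
    for f in mesh.cells[cell_id]:
        sign = mesh.face_normal_sign(f, cell_id)
        t = mesh.face_fan_triangles(f)
        vol += sign * np.einsum(
            "ij,ij->i", t[:, 0] - b, np.cross(t[:, 1] - b, t[:, 2] - b)
        ).sum() / 6.0
    if vol <= 0:
        raise TopologyError(f"cell {cell_id} has non-positive volume {vol}")
    return float(vol)


def cell_area(mesh: OrganoidMesh, cell_id: int) -> float:
    """Total surface area of one cell (μm²), all faces counted fully."""
    return float(sum(mesh.face_area(f) for f in mesh.cells[cell_id]))


def _lumen_signed(mesh: OrganoidMesh) -> float:
    """Signed apical flux from the origin (no closure check)."""
    vol = 0.0
    for f in mesh.faces_of_type(APICAL):
        t = mesh.face_fan_triangles(f)
        vol -= np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    return float(vol)


def lumen_volume(mesh: OrganoidMesh) -> float:
    """Volume enclosed by the apical surface (μm³), divergence theorem."""
    apical = mesh.faces_of_type(APICAL)
    if len(apical) == 0:
        raise TopologyError("mesh has no apical faces")
    # closure check: every apical edge must lie in exactly two apical faces
    count: dict[tuple[int, int], int] = {}
    for f in apical:
        loop = mesh.faces[f]
        for i in range(len(loop)):
            e = (int(loop[i]), int(loop[(i + 1) % len(loop)]))
            e = (min(e), max(e))
            count[e] = count.get(e, 0) + 1
    bad = [e for e, cnt in count.items() if cnt != 2]
    if bad:
        raise TopologyError(f"apical surface is not closed at edges {bad[:5]}")
    vol = 0.0
    for f in apical:
        t = mesh.face_fan_triangles(f)
        # stored apical loops are oriented toward the lumen; flip for outward
        vol -= np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    if vol <= 0:
        raise TopologyError(f"apical surface encloses non-positive volume {vol}")
    return float(vol)


# ---------------------------------------------------------------------------
# energy and gradient
# ---------------------------------------------------------------------------

def _require_reference(mesh: OrganoidMesh, params: AVMParameters) -> AVMParameters:
    if params.reference_state is None:
        return params.with_reference(mesh)
    ref = params.reference_state
    if len(ref.cell_area) != mesh.n_cells or len(ref.cell_volume) != mesh.n_cells:
        raise InvalidConfigurationError(
            "reference_state dimensions do not match the mesh's cell count"
        )
    return params


def _energy_terms(topo: _Topology, X: np.ndarray, params: AVMParameters):
    ref = params.reference_state
    klum = params.resolved_lumen_elasticity(topo.n_cells)
    face_area, face_vol = _geometry(topo, X)[-2:]

    ev = X[topo.edges[:, 0]] - X[topo.edges[:, 1]]
    el = np.linalg.norm(ev, axis=1)
    edge_term = params.line_tension * el.sum()
    face_term = params.surface_tension * face_area.sum()

    A_c = topo.inc @ face_area
    V_c = topo.inc_signed @ face_vol
    V_lum = float(topo.lumen_sign @ face_vol)
    area_term = 0.5 * params.area_elasticity * np.sum((A_c - ref.cell_area) ** 2)
    volume_term = 0.5 * params.volume_elasticity * np.sum((V_c - ref.cell_volume) ** 2)
    lumen_term = 0.5 * klum * (V_lum - ref.lumen_volume) ** 2
    return edge_term, face_term, area_term, volume_term, lumen_term


def energy(mesh: OrganoidMesh, params: AVMParameters,
           topo: _Topology | None = None) -> EnergyBreakdown:
    """Evaluate the vertex energy term by term on the current geometry."""
    params = _require_reference(mesh, params)
    topo = topo or _Topology(mesh)
    terms = _energy_terms(topo, mesh.vertices, params)
    return EnergyBreakdown(*[float(t) for t in terms])


def _gradient(topo: _Topology, X: np.ndarray, params: AVMParameters) -> np.ndarray:
    ref = params.reference_state
    klum = params.resolved_lumen_elasticity(topo.n_cells)
    cent, A, B, Cf, u, w, n, nrm, face_area, face_vol = _geometry(topo, X)

    grad = np.zeros_like(X)

    # edge term
    ev = X[topo.edges[:, 0]] - X[topo.edges[:, 1]]
    el = np.linalg.norm(ev, axis=1)
    g = params.line_tension * ev / el[:, None]
    np.add.at(grad, topo.edges[:, 0], g)
    np.add.at(grad, topo.edges[:, 1], -g)

    A_c = topo.inc @ face_area
    V_c = topo.inc_signed @ face_vol
    V_lum = float(topo.lumen_sign @ face_vol)

    # per-face weights: dE/dA_f and dE/dV_f
    w_area = (params.surface_tension
              + topo.inc.T @ (params.area_elasticity * (A_c - ref.cell_area)))
    w_vol = (topo.inc_signed.T @ (params.volume_elasticity * (V_c - ref.cell_volume))
             + topo.lumen_sign * (klum * (V_lum - ref.lumen_volume)))

    # area gradient per fan triangle: A = |u×w| / 2
    nhat = n / nrm[:, None]
    ga = 0.5 * np.cross(w, nhat)
    gb = 0.5 * np.cross(nhat, u)
    gc = -(ga + gb)
    wa = w_area[topo.tri_face][:, None]
    gcent_acc = np.zeros((topo.n_faces, 3))
    np.add.at(grad, topo.tri_a, wa * ga)
    np.add.at(grad, topo.tri_b, wa * gb)
    np.add.at(gcent_acc, topo.tri_face, wa * gc)

    # volume gradient per fan triangle: 6 V = Cf · (A × B)
    wv = w_vol[topo.tri_face][:, None] / 6.0
    np.add.at(grad, topo.tri_a, wv * np.cross(B, Cf))
    np.add.at(grad, topo.tri_b, wv * np.cross(Cf, A))
    np.add.at(gcent_acc, topo.tri_face, wv * np.cross(A, B))

    # distribute the face-centroid contributions back to the loop vertices
    grad += topo.centroid_op.T @ gcent_acc
    return grad


def energy_gradient(mesh: OrganoidMesh, params: AVMParameters,
                    topo: _Topology | None = None) -> np.ndarray:
    """Analytic gradient of the total energy w.r.t. every vertex coordinate.

    Returns an (n_vertices, 3) array in fJ/μm.
    """
    params = _require_reference(mesh, params)
    topo = topo or _Topology(mesh)
    return _gradient(topo, mesh.vertices, params)


def minimize(mesh: OrganoidMesh, params: AVMParameters, *,
             max_iter: int = 5000, grad_tol: float = 1e-6
             ) -> tuple[OrganoidMesh, RelaxationTrace]:
    """Relax the mesh by L-BFGS-B over all vertex coordinates.

    The topology (cells, faces, edges) is untouched; only vertex positions
    move.  Deterministic given identical inputs.  On non-convergence within
    ``max_iter`` iterations the best iterate is returned with termination
    reason ``"max-iterations"``.
    """
    params = _require_reference(mesh, params)
    topo = _Topology(mesh)
    shape = mesh.vertices.shape
    trace = RelaxationTrace()

    def fun(x: np.ndarray):
        X = x.reshape(shape)
        e = sum(_energy_terms(topo, X, params))
        g = _gradient(topo, X, params)
        return float(e), g.ravel()

    def cb(x: np.ndarray):
        e, g = fun(x)
        trace.energy.append(e)
        trace.grad_norm.append(float(np.max(np.abs(g))))

    e0, g0 = fun(mesh.vertices.ravel())
    trace.energy.append(e0)
    trace.grad_norm.append(float(np.max(np.abs(g0))))

    res = scipy.optimize.minimize(
        fun, mesh.vertices.ravel(), jac=True, method="L-BFGS-B",
        callback=cb, options={"maxiter": max_iter, "gtol": grad_tol,
                              "ftol": 1e-16, "maxcor": 20},
    )
    trace.n_iterations = int(res.nit)
    if res.nit >= max_iter:
        trace.termination = "max-iterations"
    elif res.success:
        trace.termination = "converged"
    else:
        trace.termination = str(res.message)

    X = res.x.reshape(shape).copy()
    relaxed = _with_vertices(mesh, X)
    return relaxed, trace


def _with_vertices(mesh: OrganoidMesh, X: np.ndarray) -> OrganoidMesh:
    return OrganoidMesh(
        vertices=X,
        vertex_layer=mesh.vertex_layer.copy(),
        faces=[f.copy() for f in mesh.faces],
        face_type=mesh.face_type.copy(),
        face_cells=list(mesh.face_cells),
        cells=[c.copy() for c in mesh.cells],
        cell_seed=mesh.cell_seed.copy(),
        seed_directions=mesh.seed_directions.copy(),
        lumen_point=X.mean(axis=0),
        radius_basal=mesh.radius_basal,
        thickness_ratio=mesh.thickness_ratio,
    )


def relax_normalized(mesh: OrganoidMesh, params: AVMParameters, *,
                     max_iter: int = 5000, grad_tol: float = 1e-3
                     ) -> tuple[OrganoidMesh, RelaxationTrace]:
    """Relax on the normalized (unit basal radius) sphere, then restore scale.

    The seed lattice is built on the unit sphere and physical dimensions are
    applied afterwards; relaxing at the normalized scale keeps the elastic
    terms (quadratic in μm³-scale volumes) and the tension terms numerically
    commensurate, which the dimensioned organoid scale does not.
    """
    if not mesh.radius_basal:
        raise InvalidConfigurationError("mesh carries no basal radius to normalize by")
    s = 1.0 / mesh.radius_basal
    scaled = _with_vertices(mesh, mesh.vertices * s)
    scaled.radius_basal = 1.0
    relaxed, trace = minimize(scaled, params.with_reference(scaled),
                              max_iter=max_iter, grad_tol=grad_tol)
    out = _with_vertices(mesh, relaxed.vertices / s)
    out.lumen_point = out.vertices.mean(axis=0)
    return out, trace
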