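"""Built-in quasi-static linear elasticity on 4-node tetrahedra.

A deliberately small solver covering exactly the load families the organoid
model uses — surface pressure, isotropic thermal eigenstrain ("active
contraction") and prescribed nodal displacements — on constant-strain
tetrahedra, so load plans can be exercised end-to-end and per-cell stress /
strain fields produced without external software.

Scope: small strain, isotropic linear elasticity, direct sparse solve.
Quadratic elements, shells and trusses are excluded on purpose (the input
deck carries them for an external solver); cortex contraction is
approximated as eigenstrain in the boundary-adjacent cytoplasm layer.
Viscoelasticity is not time-integrated; the solver evaluates the elastic
(long-time) state.

Unit system: lengths μm, moduli and stresses MPa, pressures given in Pa and
converted (× 1e-6) internally; the implied force unit is μN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import avm
from .errors import InvalidConfigurationError, SolverError
from .femgen import (
    BLOCK_CYTOPLASM,
    BLOCK_LUMEN,
    CORTEX_BLOCK,
    LoadPlan,
    MaterialSpec,
    PrescribedDisplacement,
    SubcellularMesh,
    SurfacePressure,
    TemperatureLoad,
)
from .shell_builder import APICAL, BASAL, LATERAL, OrganoidMesh

PA_TO_MPA = 1e-6


# ---------------------------------------------------------------------------
# problem and solution containers
# ---------------------------------------------------------------------------

@dataclass
class FEProblem:
    """Linear-tetra elasticity problem.

    ``pressure_tris`` are corner-node triangles oriented so their right-hand
    normal points along the direction of positive pressure (outward from the
    loaded cell); ``pressure_pa`` is in Pa.  ``temperature`` is the relative
    temperature (a.u.) per element, acting through ``alpha`` as the isotropic
    eigenstrain α·ΔT·I.
    """

    nodes: np.ndarray                  # (N, 3) μm
    tets: np.ndarray                   # (M, 4) node ids
    young: np.ndarray                  # (M,) MPa
    poisson: np.ndarray                # (M,)
    alpha: np.ndarray | None = None    # (M,) expansion per a.u.
    temperature: np.ndarray | None = None   # (M,) a.u.
    pressure_tris: np.ndarray | None = None  # (P, 3) node ids
    pressure_pa: np.ndarray | None = None    # (P,)
    constraints: list[tuple[int, int, float]] = field(default_factory=list)
    auto_tie_down: bool = True
    element_ids: np.ndarray | None = None    # optional global ids (M,)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)


@dataclass
class FESolution:
    """Displacements, per-element constant strain/stress and von Mises."""

    displacements: np.ndarray    # (N, 3) μm
    strain: np.ndarray           # (M, 6) tensor components 11,22,33,12,13,23
    stress: np.ndarray           # (M, 6) MPa
    von_mises: np.ndarray        # (M,) MPa
    residual: float              # ‖Ku−f‖/‖f‖
    tie_down_nodes: tuple[int, ...] = ()

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).max())


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _tet_geometry(nodes: np.ndarray, tets: np.ndarray):
    """Volumes and shape-function gradients of all elements.

    Returns (vol (M,), grads (M, 4, 3)); raises on inverted elements.
    """
    p = nodes[tets]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    d3 = p[:, 3] - p[:, 0]
    vol6 = np.einsum("ij,ij->i", d1, np.cross(d2, d3))
    if np.any(vol6 <= 0):
        bad = int(np.argmax(vol6 <= 0))
        raise SolverError(f"inverted or degenerate element {bad} (6V = {vol6[bad]})")
    J = np.stack([d1, d2, d3], axis=1)          # (M, 3, 3) rows = edge vectors
    Jinv = np.linalg.inv(J)
    # gradients of barycentric shape functions N1..N3 are rows of Jinv^T
    g123 = np.transpose(Jinv, (0, 2, 1))        # (M, 3, 3): grad N2, N3, N4
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (M, 4, 3)
    return vol6 / 6.0, grads


def _b_matrices(grads: np.ndarray) -> np.ndarray:
    """Voigt strain-displacement matrices (M, 6, 12), engineering shear."""
    M = len(grads)
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c] = gz
        B[:, 4, c + 2] = gx
        B[:, 5, c + 1] = gz
        B[:, 5, c + 2] = gy
    return B


def _d_matrices(young: np.ndarray, poisson: np.ndarray) -> np.ndarray:
    """Isotropic elasticity matrices (M, 6, 6) in Voigt engineering shear."""
    lam = young * poisson / ((1 + poisson) * (1 - 2 * poisson))
    mu = young / (2 * (1 + poisson))
    M = len(young)
    D = np.zeros((M, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu
    return D


def assemble(problem: FEProblem):
    """Assemble the sparse stiffness matrix and consistent load vector.

    Pressure loads contribute p·A/3 per triangle node along the triangle's
    right-hand normal; eigenstrain loads contribute Bᵀ·D·ε0·V with
    ε0 = α·ΔT·[1,1,1,0,0,0].
    """
    nodes, tets = problem.nodes, problem.tets
    vol, grads = _tet_geometry(nodes, tets)
    B = _b_matrices(grads)
    D = _d_matrices(problem.young, problem.poisson)
    Ke = np.einsum("mji,mjk,mkl,m->mil", B, D, B, vol)

    dof = (3 * tets[:, :, None] + np.arange(3)[None, None, :]).reshape(len(tets), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(3 * len(nodes), 3 * len(nodes))).tocsr()

    f = np.zeros(3 * len(nodes))
    if problem.temperature is not None and problem.alpha is not None:
        e0 = np.zeros((len(tets), 6))
        e0[:, :3] = (problem.alpha * problem.temperature)[:, None]
        fe = np.einsum("mji,mjk,mk,m->mi", B, D, e0, vol)
        np.add.at(f, dof.ravel(), fe.ravel())
    if problem.pressure_tris is not None and len(problem.pressure_tris):
        tri = problem.pressure_tris
        p = nodes[tri]
        n2 = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # |n2| = 2·area
        fnode = (problem.pressure_pa * PA_TO_MPA / 6.0)[:, None] * n2
        for k in range(3):
            np.add.at(f, 3 * tri[:, k], fnode[:, 0])
            np.add.at(f, 3 * tri[:, k] + 1, fnode[:, 1])
            np.add.at(f, 3 * tri[:, k] + 2, fnode[:, 2])
    return K, f


def boundary_triangles(tets: np.ndarray) -> np.ndarray:
    """Outward-oriented boundary faces of a positively oriented tet mesh.

    Nodal pressure loads are consistent with an interior stress state only
    when the loaded surface triangulation coincides with the tet boundary
    faces, so exact-solution benchmarks should load these triangles.
    """
    faces: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    for a, b, c, d in tets:
        for tri in ((a, c, b), (a, b, d), (b, c, d), (a, d, c)):
            key = tuple(sorted(tri))
            if key in faces:
                del faces[key]
            else:
                faces[key] = tri
    return np.asarray(list(faces.values()), dtype=np.int64)


def _rigid_fit(nodes: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Best-fit infinitesimal rigid motion t + ω × x of a displacement field."""
    n = len(nodes)
    A = np.zeros((3 * n, 6))
    A[0::3, 0] = A[1::3, 1] = A[2::3, 2] = 1.0
    x, y, z = nodes.T
    A[0::3, 4] = z
    A[0::3, 5] = -y
    A[1::3, 3] = -z
    A[1::3, 5] = x
    A[2::3, 3] = y
    A[2::3, 4] = -x
    coef, *_ = np.linalg.lstsq(A, u.ravel(), rcond=None)
    return (A @ coef).reshape(-1, 3)


def _auto_tie_down(nodes: np.ndarray) -> list[tuple[int, int, float]]:
    """Statically determinate 3-2-1 restraint for self-equilibrated loads."""
    a = 0
    d = np.linalg.norm(nodes - nodes[a], axis=1)
    b = int(np.argmax(d))
    ab = nodes[b] - nodes[a]
    ab /= np.linalg.norm(ab)
    off = nodes - nodes[a] - np.outer((nodes - nodes[a]) @ ab, ab)
    c = int(np.argmax(np.linalg.norm(off, axis=1)))
    # node a: all three axes; node b: the two axes most orthogonal to ab;
    # node c: the axis most parallel to the plane normal
    axes_b = np.argsort(np.abs(ab))[:2]
    n = np.cross(ab, nodes[c] - nodes[a])
    n /= np.linalg.norm(n)
    axis_c = int(np.argmax(np.abs(n)))
    cons = [(a, 0, 0.0), (a, 1, 0.0), (a, 2, 0.0)]
    cons += [(b, int(ax), 0.0) for ax in axes_b]
    cons.append((c, axis_c, 0.0))
    return cons


def solve(problem: FEProblem) -> FESolution:
    """Direct sparse solve; residual ‖Ku−f‖/‖f‖ < 1e-8 enforced.

    With fewer than 6 constraints and ``auto_tie_down`` enabled, a
    statically determinate 3-2-1 restraint is added automatically (intended
    for self-equilibrated load states such as closed shells under pressure).
    """
    cons = list(problem.constraints)
    tie_nodes: tuple[int, ...] = ()
    if len(cons) < 6:
        if not problem.auto_tie_down:
            raise SolverError(
                "fewer than 6 constraints and auto_tie_down disabled: "
                "rigid-body modes are unconstrained")
        extra = _auto_tie_down(problem.nodes)
        tie_nodes = tuple(sorted({n for n, _, _ in extra}))
        cons += extra

    K, f = assemble(problem)
    ndof = 3 * problem.n_nodes
    fixed = np.array([3 * n + ax for n, ax, _ in cons], dtype=int)
    if len(np.unique(fixed)) != len(fixed):
        raise InvalidConfigurationError("duplicate constraints on the same dof")
    vals = np.array([v for _, _, v in cons])
    free = np.setdiff1d(np.arange(ndof), fixed)

    u = np.zeros(ndof)
    u[fixed] = vals
    rhs = f[free] - K[free][:, fixed] @ vals
    Kff = K[free][:, free].tocsc()
    try:
        u[free] = spla.spsolve(Kff, rhs)
    except RuntimeError as exc:
        raise SolverError(f"singular system (rigid-body mode?): {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise SolverError("singular system: non-finite displacements "
                          "(rigid-body-mode diagnosis: add constraints)")
    res_vec = K[free] @ u - f[free]
    scale = np.linalg.norm(f) if np.linalg.norm(f) > 0 else 1.0
    residual = float(np.linalg.norm(res_vec) / scale)
    if residual > 1e-8:
        raise SolverError(f"solver residual {residual:.2e} exceeds 1e-8")

    if tie_nodes:
        # the statically determinate tie-down leaves the deformation field
        # unique only up to a rigid motion pinned at arbitrary nodes;
        # normalize by projecting out the best-fit infinitesimal rigid motion
        # (strains and stresses are unaffected)
        u = u - _rigid_fit(problem.nodes, u.reshape(-1, 3)).ravel()

    vol, grads = _tet_geometry(problem.nodes, problem.tets)
    B = _b_matrices(grads)
    D = _d_matrices(problem.young, problem.poisson)
    dof = (3 * problem.tets[:, :, None]
           + np.arange(3)[None, None, :]).reshape(len(problem.tets), 12)
    ue = u[dof]
    eps_voigt = np.einsum("mij,mj->mi", B, ue)     # engineering shear
    e0 = np.zeros_like(eps_voigt)
    if problem.temperature is not None and problem.alpha is not None:
        e0[:, :3] = (problem.alpha * problem.temperature)[:, None]
    sig = np.einsum("mij,mj->mi", D, eps_voigt - e0)
    vm = np.sqrt(0.5 * ((sig[:, 0] - sig[:, 1]) ** 2
                        + (sig[:, 1] - sig[:, 2]) ** 2
                        + (sig[:, 2] - sig[:, 0]) ** 2
                        + 6.0 * (sig[:, 3:] ** 2).sum(axis=1)))
    strain = eps_voigt.copy()
    strain[:, 3:] *= 0.5   # tensor shear components
    return FESolution(displacements=u.reshape(-1, 3), strain=strain,
                      stress=sig, von_mises=vm, residual=residual,
                      tie_down_nodes=tie_nodes)


# ---------------------------------------------------------------------------
# load-plan execution on the organoid submesh
# ---------------------------------------------------------------------------

@dataclass
class PlanResult:
    """Per-step solver output and the deformed vertex-model surfaces."""

    solutions: list[FESolution]
    deformed_meshes: list[OrganoidMesh]
    element_ids: np.ndarray   # global ids of the solved linear elements


def _linear_problem(sub: SubcellularMesh, materials: list[MaterialSpec],
                    nodes: np.ndarray, loads) -> tuple[FEProblem, np.ndarray]:
    """Build the compact linear-tet problem (corner/centroid nodes only).

    Mid-edge nodes carry no stiffness in the linear subproblem; they are
    excluded here and re-interpolated after the solve.  Returns the problem
    plus the used-node index array mapping compact ids to submesh ids.
    """
    mats = {m.name: m for m in materials}
    cyto = sub.blocks[BLOCK_CYTOPLASM]
    lum = sub.blocks[BLOCK_LUMEN]
    tets = np.vstack([cyto.connectivity[:, :4], lum.connectivity])
    eids = np.concatenate([cyto.element_ids, lum.element_ids])
    young = np.concatenate([
        np.full(len(cyto), mats[BLOCK_CYTOPLASM].young_modulus),
        np.full(len(lum), mats[BLOCK_LUMEN].young_modulus)])
    poisson = np.concatenate([
        np.full(len(cyto), mats[BLOCK_CYTOPLASM].poisson_ratio),
        np.full(len(lum), mats[BLOCK_LUMEN].poisson_ratio)])

    # cortex temperature -> eigenstrain in boundary-adjacent cytoplasm tets;
    # each cytoplasm tet's first node is its face-centroid, identifying the
    # face (hence face type) it abuts
    mesh = sub.source
    nv = mesh.n_vertices
    face_of_tet = cyto.connectivity[:, 0] - nv
    ftype_of_tet = mesh.face_type[face_of_tet]
    alpha = np.zeros(len(tets))
    temperature = np.zeros(len(tets))
    pressure_tris = []
    pressure_vals = []
    constraints: list[tuple[int, int, float]] = []
    for ld in loads:
        if isinstance(ld, TemperatureLoad):
            ftype = {v: k for k, v in CORTEX_BLOCK.items()}.get(ld.region)
            if ftype is None:
                raise InvalidConfigurationError(
                    f"temperature load region {ld.region!r} is not a cortex set")
            sel = np.flatnonzero(ftype_of_tet == ftype)
            alpha[sel] = mats[ld.region].expansion or 0.0
            temperature[sel] = ld.value
        elif isinstance(ld, SurfacePressure):
            if ld.region not in sub.surfaces:
                raise InvalidConfigurationError(
                    f"pressure load region {ld.region!r} is not a surface")
            tris = sub.surfaces[ld.region]
            pressure_tris.append(tris)
            pressure_vals.append(np.full(len(tris), ld.pascals))
        elif isinstance(ld, PrescribedDisplacement):
            for node, u in ld.displacements.items():
                for ax in range(3):
                    constraints.append((int(node), ax, float(u[ax])))

    used = np.unique(tets)
    remap = np.full(len(nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    problem = FEProblem(
        nodes=nodes[used], tets=remap[tets], young=young, poisson=poisson,
        alpha=alpha, temperature=temperature,
        pressure_tris=remap[np.vstack(pressure_tris)] if pressure_tris else None,
        pressure_pa=np.concatenate(pressure_vals) if pressure_vals else None,
        constraints=[(int(remap[n]), ax, v) for n, ax, v in constraints],
        element_ids=eids,
    )
    return problem, used


def solve_plan(sub: SubcellularMesh, materials: list[MaterialSpec],
               plan: LoadPlan, max_step_displacement_fraction: float = 0.5
               ) -> PlanResult:
    """Apply a load plan cumulatively, re-solving on updated geometry.

    After each step all submesh nodes are displaced by the solution and the
    vertex-model surfaces are rebuilt from the displaced corner nodes, ready
    for morphometric analysis.  A step whose maximum displacement exceeds
    ``max_step_displacement_fraction`` × basal radius aborts with advice to
    subdivide the load.
    """
    mesh = sub.source
    if mesh is None:
        raise InvalidConfigurationError("submesh carries no source mesh")
    center = mesh.vertices.mean(axis=0)
    radius = float(np.linalg.norm(
        mesh.vertices[mesh.vertex_layer == BASAL] - center, axis=1).mean())
    nodes = sub.nodes.copy()
    solutions = []
    deformed = []
    eids = None
    for step in plan.steps:
        problem, used = _linear_problem(sub, materials, nodes, step.loads)
        eids = problem.element_ids
        sol = solve(problem)
        if sol.max_displacement > max_step_displacement_fraction * radius:
            raise SolverError(
                f"step {step.name!r}: max displacement {sol.max_displacement:.3g} μm "
                f"exceeds {max_step_displacement_fraction:.0%} of the organoid radius; "
                "subdivide the load into smaller steps")
        u_full = np.zeros_like(nodes)
        u_full[used] = sol.displacements
        for (a, b), m in sub.mid_edge.items():
            u_full[m] = 0.5 * (u_full[a] + u_full[b])
        nodes = nodes + u_full
        sol = FESolution(displacements=u_full, strain=sol.strain,
                         stress=sol.stress, von_mises=sol.von_mises,
                         residual=sol.residual, tie_down_nodes=sol.tie_down_nodes)
        solutions.append(sol)
        deformed.append(avm._with_vertices(mesh, nodes[:mesh.n_vertices].copy()))
    return PlanResult(solutions=solutions, deformed_meshes=deformed,
                      element_ids=eids)


def export_field_table(path, result: PlanResult, sub: SubcellularMesh,
                       step: int = -1) -> None:
    """Write one step's element fields in the neutral CSV dialect."""
    from .abaqus_io import write_field_table
    sol = result.solutions[step]
    write_field_table(path, result.element_ids, sol.von_mises, sol.strain)


# ---------------------------------------------------------------------------
# structured validation mesh
# ---------------------------------------------------------------------------

def thick_sphere_mesh(inner_radius: float, outer_radius: float,
                      n_directions: int = 400, n_layers: int = 3,
                      grading: str = "geometric"):
    """Structured tet mesh of a thick spherical shell (validation helper).

    Directions come from a golden-angle lattice triangulated by its convex
    hull; radial layers are geometrically graded toward the inner wall by
    default (``grading="uniform"`` for equal spacing), where pressure-driven
    fields vary fastest.  Each triangular prism is split into 3 tetrahedra
    with face diagonals chosen by smallest global node id, which keeps
    neighbouring prisms conforming.

    Returns (nodes, tets, inner_tris, outer_tris); the boundary triangles
    are oriented with right-hand normals pointing radially outward.
    """
    from .shell_builder import fibonacci_seeds, spherical_delaunay
    seeds = fibonacci_seeds(n_directions, 0.0, 0)
    tri = spherical_delaunay(seeds)
    dirs = seeds.unit_vectors
    if grading == "geometric":
        radii = inner_radius * (outer_radius / inner_radius) ** (
            np.arange(n_layers + 1) / n_layers)
    elif grading == "uniform":
        radii = np.linspace(inner_radius, outer_radius, n_layers + 1)
    else:
        raise InvalidConfigurationError(f"unknown grading {grading!r}")
    nodes = np.vstack([dirs * r for r in radii])
    n = n_directions

    def split_prism(p):
        perms = [(0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
                 (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0)]
        best = min(perms, key=lambda pe: p[pe[0]])
        q = [p[i] for i in best]
        if min(q[1], q[5]) < min(q[2], q[4]):
            tets = [(q[0], q[1], q[2], q[5]), (q[0], q[1], q[5], q[4]),
                    (q[0], q[4], q[5], q[3])]
        else:
            tets = [(q[0], q[1], q[2], q[4]), (q[0], q[4], q[2], q[5]),
                    (q[0], q[4], q[5], q[3])]
        return tets

    all_tets = []
    for layer in range(n_layers):
        lo = layer * n
        hi = (layer + 1) * n
        for a, b, c in tri:
            all_tets.extend(split_prism(
                (lo + a, lo + b, lo + c, hi + a, hi + b, hi + c)))
    tets = np.asarray(all_tets, dtype=np.int64)
    # fix orientation by volume sign
    p = nodes[tets]
    vol6 = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                     np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]))
    flip = vol6 < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]

    inner = tri.copy()                    # outward-oriented on the unit sphere
    outer = tri + n_layers * n
    return nodes, tets, inner, outer
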