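# Methods

`organoidvm` models a closed, single-layered epithelial sphere — an organoid
with a central lumen — as a 3D vertex model, equips it with a subcellular
finite-element discretization, and measures per-cell geometry and mechanics.
This note records the model, the numerical choices, and what the synthetic
constructions do and do not capture about real organoids.

## Shell construction

Seeds are placed on the unit sphere with the golden-angle (Fibonacci)
lattice, point *i* at

    z = 1 − 2(i + ½)/n,   r = √(1 − z²),   θ = i·π(3 − √5).

A tangent-plane Gaussian jitter makes the lattice biologically irregular; its
standard deviation is `jitter_sigma` × (mean nearest-neighbour angular
spacing of the jitter-free lattice), applied in an orthonormal tangent frame
and renormalized.  The default `jitter_sigma = 0.2` produces visibly
non-uniform cells without topological degeneracies; the jitter amplitude and
space (angular vs Cartesian) are this package's choices, since only the use
of "a normal deviation" is documented for the original construction.

The Delaunay triangulation of the sphere is the convex hull of the seeds
(`scipy.spatial.ConvexHull`), oriented outward.  The Voronoi dual is built
explicitly: the Voronoi vertex of each triangle is its unit-normalized
circumcenter, and each seed's polygon is the cyclic walk over its incident
triangles, counterclockwise seen from outside.  Triangles whose spherical
circumradius reaches π/2 abort with a degeneracy error, as do seeds with
fewer than three incident triangles.  `scipy.spatial.SphericalVoronoi` is
used in the test suite as an independent cross-check of the cell solid
angles, never as the implementation.

Extrusion duplicates the Voronoi shell at two radii — basal (outer) at the
organoid radius `R`, apical (inner) at `R·(1 − t)` with thickness ratio
`t = (R_basal − R_apical)/R_basal` — and connects neighbouring cells with one
shared lateral quad per Voronoi edge.  Stage presets use t = 0.07 / 0.25 /
0.4 (immature / intermediate / mature) with stage radii 229.2 / 114.2 /
187.2 μm, the half-mean measured diameters of the corresponding organoid
stages.

Conventions used everywhere downstream: right-handed Cartesian μm with the
shell centroid at the origin; every polygonal face fan-triangulated from its
vertex centroid; face loops stored oriented outward from the owning cell
(for lateral faces, outward from the lower-id owner).  Degenerate Voronoi
polygons abort generation with a seed/jitter diagnostic rather than being
repaired silently.

## Active vertex energy

The monolayer's quasi-static mechanics is the energy

    E = Λ Σ_e l_e + T_f Σ_f A_f
        + Σ_c [ K_A/2 (A_c − A_c0)² + K_V/2 (V_c − V_c0)² ]
        + K_lum/2 (V_lum − V_lum0)²

with sums over geometric edges and faces taken once (not per-cell
half-entities), while per-cell area A_c and volume V_c count shared faces
fully for each owner; the alternative half-edge bookkeeping would only
rescale Λ and T_f.  Defaults: Λ = 50 fJ/μm, T_f = 10 fJ/μm², K_A =
1000 fJ/μm⁴, K_V = 1000 fJ/μm⁹, K_lum = 0.001 × cell count (units as
printed in the source parameter table).  The tabulated "contractility"
(0.1 nN·μm) has no term in the printed energy; it is stored and echoed but
not evaluated.  The reference state (A_c0, V_c0, V_lum0) is captured from
the pre-relaxation mesh by default and overridable.

Because the fan triangulation closes every cell boundary for arbitrary
vertex positions, signed volumes are evaluated from the coordinate origin;
the value is identical to the tetrahedra-from-cell-centroid definition and
reference-point free, which also simplifies the analytic gradient.  The
gradient is exact (edge direction vectors; triangle-area gradients with
centroid chain rule; triple-product volume gradients) and is verified
against central finite differences to better than 1e-5 relative.

Minimization is quasi-Newton (L-BFGS-B) over all vertex coordinates with
the analytic gradient; connectivity never changes (no T1/T2 transitions, no
division).  Defaults: `max_iter = 5000`, `grad_tol = 1e-6` fJ/μm per
coordinate for `minimize`.  **Scale choice:** at the dimensioned organoid
scale (R ≈ 175 μm, V_c ≈ 3·10⁴ μm³) the quadratic elastic terms are ~10⁶
times stiffer than the tension terms and L-BFGS-B creeps without reaching
stationarity.  The lattice is natively built on the normalized sphere, so
`relax_normalized` rescales the mesh to unit basal radius, relaxes there
(where the terms are commensurate and convergence to `grad_tol = 1e-3`
takes a few hundred iterations), and restores the physical scale.  The
pipeline relaxes this way.

## Morphometric descriptors

Per cell: volume; apical, basal and lateral areas (fan-triangulated,
grouped by face type); apical/lateral and basal/lateral ratios (NaN when
the lateral area is zero); volume-weighted centroid of the tetra
decomposition; and the spreading distance — the mean Euclidean distance to
the k = 5 nearest cell centroids (k exposed as a parameter).  The measured
thickness ratio is (mean basal − mean apical vertex radius)/mean basal
radius about the mesh centroid; under jitter the centroid sits slightly off
the origin, so the measure deviates from the construction value at second
order (~10⁻⁸).

The label-image route consumes segmented 3D rasters (cells + lumen label +
background): volume = voxel count × voxel volume; apical/basal/lateral area
= 6-connected voxel faces shared with lumen/background/other cells; voxel-
center-mean centroids; labels touching the raster boundary are flagged
(their basal areas are underestimates) rather than dropped.  Voxel-face
areas overestimate smooth areas by up to ~1.5× (digitization bias), so
label-route areas are for within-method comparison.

`voxelize_organoid` is the package's stand-in for segmented microscopy: each
voxel center strictly between the surfaces gets the nearest seed direction's
cell label; surface radii per direction are the nearest positive
intersection of the radial ray with the assigned cell's fan-triangle planes
(valid because the shell surfaces are star-shaped about the centroid).  At
1 μm voxels, per-cell voxel volumes agree with mesh volumes within 10% for
cells ≥ 500 μm³.  Real segmented data differ in ways this fixture does not
emulate: anisotropic PSF, segmentation errors, non-radial cell boundaries,
open or multiple lumina — so passing cross-validation shows the measurement
code is consistent, not that segmentation noise is handled.

## Subcellular FEM discretization

Each cell becomes: quadratic 10-node tetrahedra for the cytoplasm (one per
face fan-triangle, connecting cell centroid, face centroid and two polygon
vertices — the fan construction is this package's concretization of
"connecting the centroid of the cell and part of the cell face"); quadratic
6-node membrane triangles on the boundary fans, grouped apical / basal /
lateral and reusing only cytoplasm nodes; 3-node cortex line elements
(corner–midedge–corner) ringing every polygon; and linear 4-node lumen
tetrahedra fanning the apical surface from a lumen-centroid node, corner
nodes only (accepting hanging mid-edge nodes at the apical interface).
Cell–cell interfaces are single sheets, not duplicated.  Mid-edge nodes sit
at exact midpoints and are shared across all incident elements.  Per-cell
tetra volumes reproduce the vertex-model volumes exactly (same
decomposition), checked to 1e-9 relative.

The cortex element class is 3-node thermal truss (T3D3T) by default with an
S3RT shell variant behind a deck option: the running text and the element
figure say truss while the material table prints S3RT; the table is treated
as the likely typo.

The eight-material library is reproduced verbatim from the source table
(moduli in MPa; cytoplasm E = 2.1 kPa, ν = 0.39 ... lumen E = 4 Pa,
ν = 0.25).  The running text's "21 kPa" for cytoplasm conflicts with the
table's 2.10E-03 MPa; defaults follow the table, and a material-override
mechanism exposes every field.  Mass density is carried as printed — its
unit is ambiguous — and is inert in quasi-static analyses.  The printed
viscous modulus 0.01 / relaxation rate 0.3 are mapped to a single-term
normalized shear relaxation pair (modulus ratio g₁ = 0.01, relaxation time
τ₁ = 0.3); this is an interpretation and is flagged as such in the deck.

### Load plans

Three load families: surface pressure (Pa, positive = outward from the
cell, normal to the element); active contraction as a relative
"temperature" in arbitrary units driving the cortex's thermal expansion
(decorrelated from physical temperature); and prescribed nodal
displacements.  The three-step maturation plan carries the printed
magnitudes (step 1: apical +90 Pa, basal −500 Pa, lateral cortex −100 a.u.;
step 2: lateral cortex 0, apical/basal cortex +100 a.u., apical −0.9 kPa,
basal −1 kPa; step 3: apical cortex −300, basal +400, lateral +100 a.u.,
apical −1.85 kPa, basal −1.21 kPa).  The step-2 pressure pair is assigned
apical/basal in printed order; the source text does not make the assignment
explicit.  The swelling plan scales caller-supplied base pressures threefold
in step 2 (the base magnitudes are not printed in the source).

The "inverted Poisson's law" displacement kernel is unspecified at source;
this package uses K(rank) = λ^rank/rank! normalized to 1 at the pole, with
rank = round(geodesic distance / dist_scale), dist_scale defaulting to
R·π/16 and rate λ = 0.8 (λ < 1 enforced so the kernel decays
monotonically); the kernel is pluggable.

### Deck emission

One keyword text file: nodes, element blocks typed C3D10M / STRI65 / T3D3T
(or S3RT) / C3D4, element sets named by material, node sets, element-based
apical/basal surfaces, material blocks (elastic, density, expansion +
specific heat for cortex, Prony viscoelastic record), nominal shell
thickness 0.1 μm and truss cross-section 0.1 μm² (required by the format;
the source states neither), one solver step per plan step — coupled
temperature-displacement whenever a step carries temperature loads, static
otherwise.  Lengths are μm, moduli MPa, pressures converted Pa → MPa
(×1e-6) on write.  Output is byte-identical for identical inputs, and a
parser reads decks back for round-trip count/load/material verification.

## Built-in solver

A deliberately small quasi-static linear-elasticity solver on constant-
strain (4-node) tetrahedra covers the cytoplasm + lumen blocks with all
three load families, so plans can be exercised without external software:
standard B-matrix assembly, isotropic D, consistent pressure loads
(p·A/3 per triangle node along the outward normal), isotropic eigenstrain
ε₀ = αΔT·I, direct sparse solve, residual ‖Ku−f‖/‖f‖ < 1e-8 enforced.
Quadratic elements, shells and trusses are deliberately excluded (they go
to the external solver via the deck); cortex contraction is approximated as
eigenstrain in the boundary-adjacent cytoplasm layer — each cytoplasm tetra
abuts exactly one face, whose type selects the cortex expansion
coefficient.  How faithfully that surrogate tracks true truss contraction
is unquantified; it is qualitative only.  Viscoelasticity is not
time-integrated; the solver evaluates the elastic (long-time) state.

Closed shells under self-equilibrated pressure get an automatic statically
determinate 3-2-1 tie-down; because it pins arbitrary nodes, the reported
displacements are normalized by projecting out the best-fit infinitesimal
rigid motion (strains and stresses are unaffected).

Verification: a uniaxial patch test is exact to machine precision (constant-
strain elements reproduce constant stress states exactly); uniform free
thermal expansion is stress-free; global equilibrium holds to 1e-8; and the
thick-walled-sphere (Lamé) benchmark at inner/outer radius 50/100 μm under
1 kPa internal pressure matches the closed-form radial displacement within
2% at both surfaces.  Constant-strain tetrahedra converge only linearly in
stress, so 2% requires ~40k elements (850 directions × 8 radial layers,
geometrically graded toward the inner wall where u ~ 1/r² is steepest);
that mesh solves in ~15 s.

`solve_plan` applies steps cumulatively on updated geometry, rebuilds the
vertex-model surfaces from displaced corner nodes after each step for
morphometric analysis, and aborts if a step moves any node more than half
the organoid radius, advising load subdivision.  With the library's soft,
shell-free cytoplasm the full maturation pressures (≈1 kPa) exceed that
guard — the load-bearing membranes exist only in the exported deck — so the
in-house solver is exercised with the pressure-swelling plan, where
increasing basal pressure over three magnitudes (5/50/500 Pa on a 50-cell
shell) monotonically inflates total and per-cell volumes, the qualitative
counterpart of the osmotic swelling assay.

## Pipeline and reproducibility

`run_pipeline` executes generate → relax → femgen → export-inp
(+ minisolve for pressure plans) → descriptors; every artifact is listed in
a manifest with its checksum, the configuration hash and the tool version.
All randomness flows through one integer seed; identical configurations
yield byte-identical meshes, decks and tables.  Configuration is one YAML
document with unit-suffixed keys, echoed in full at startup.

Problem sizes used by the test suite and the acceptance script — 12–100
cell shells for unit and relaxation checks, the 400-cell organoid for
meshing and deck round-trips, ~40k tetrahedra for the Lamé benchmark, 1 μm
voxelization of a 50-cell, 60 μm shell — are the package's choices for
routine verification; all scale up linearly by configuration.

## Known limitations

* No topological transitions, cell division, growth, or non-spherical
  initial topologies.
* The built-in solver is geometrically linear (small strain) and omits
  shells/trusses; headline coupled-field stress maps require the external
  solver the deck targets.
* Porous-elastic and superelastic constitutive records are out of scope
  (the source investigates and rejects them).
* Label-image descriptors assume isotropic-ish rasters and use voxel-face
  area counting with its known digitization bias.
* The AVM relaxation equilibrates at the normalized scale; at the
  dimensioned scale the printed coefficients make the landscape too stiff
  for quasi-Newton descent to reach stationarity.
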