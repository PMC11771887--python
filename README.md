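# organoidvm

A vertex-model + finite-element toolchain for spherical monolayer organoids
— closed single-cell-layer epithelial spheres enclosing a central lumen, as
grown from human colon crypts in Matrigel.  The package is for computational
tissue-biomechanics work: it generates in-silico organoids, relaxes them
under an active-vertex energy, converts them into a subcellular FEM model
with materials and load plans (osmotic pressure, active cortical
contraction, external solicitation), solves small cases with a built-in
linear tetrahedral elasticity solver, and measures per-cell morphometric and
stress/strain descriptors from meshes or segmented 3D label images.

## The model

**Geometry.** Seeds are spread on the unit sphere by the golden-angle
(Fibonacci) lattice with tangent-plane Gaussian jitter; their convex hull is
the spherical Delaunay triangulation, whose dual (normalized circumcenters,
walked cyclically per seed) tessellates the sphere into one Voronoi polygon
per cell.  The shell is extruded between two radii — basal (outer) at the
organoid radius R and apical (inner) at R(1 − t), thickness ratio
t = (R_basal − R_apical)/R_basal; t = 0.07, 0.25, 0.4 model the immature,
intermediate and mature organoid stages.

**Mechanics (active vertex model).** Vertex positions minimize

    E = Λ Σ_e l_e + T_f Σ_f A_f
        + Σ_c [ K_A/2 (A_c − A_c0)² + K_V/2 (V_c − V_c0)² ]
        + K_lum/2 (V_lum − V_lum0)²

(edge line tension, face surface tension, per-cell area and volume
elasticity, lumen compressibility) by quasi-Newton (L-BFGS-B) descent with
an exact analytic gradient.  Defaults: Λ = 50 fJ/μm, T_f = 10 fJ/μm²,
K_A = 1000 fJ/μm⁴, K_V = 1000 fJ/μm⁹, K_lum = 0.001 × cell count.

**FEM.** Each cell becomes quadratic tetrahedra (cytoplasm), quadratic
triangle membranes (apical/basal/lateral, single shared sheets at cell–cell
contacts), 3-node cortex rings and linear lumen tetrahedra, with an
eight-material library and ready-made load plans: a three-step maturation
sequence and a two-step osmotic swelling assay (threefold pressure
increase).  Decks export as solver-ready keyword text; the built-in solver
covers pressure/eigenstrain/displacement loads on the linear sub-mesh and is
validated against the uniaxial patch test and the Lamé thick-sphere closed
form.

## Worked example

```python
from organoidvm import generate_organoid, SeedConfig, avm, morphometrics as mm

cfg = SeedConfig(n_seeds=400, jitter_sigma=0.2, rng_seed=0,
                 radius_basal=114.2, thickness_ratio=0.25)   # intermediate stage
mesh = generate_organoid(cfg)
print(f"cells: {mesh.n_cells}")
print(f"measured thickness ratio: {mm.thickness_ratio_measure(mesh):.4f}")
print(f"lumen volume: {avm.lumen_volume(mesh):.0f} um^3")
table = mm.mesh_descriptors(mesh)
print(f"mean cell volume: {table.volume_um3.mean():.0f} um^3")
print(f"mean apical area: {table.apical_area_um2.mean():.1f} um^2")
print(f"mean spreading distance: {table.spreading_distance_um.mean():.1f} um")
relaxed, trace = avm.relax_normalized(mesh, avm.AVMParameters())
print(f"energy {trace.energy[0]:.1f} -> {trace.energy[-1]:.1f} fJ (normalized scale)")
```

prints

```
cells: 400
measured thickness ratio: 0.2500
lumen volume: 2595942 um^3
mean cell volume: 8894 um^3
mean apical area: 229.1 um^2
mean spreading distance: 18.8 um
energy 22536.7 -> 8036.0 fJ (normalized scale)
```

A 400-seed shell yields one cell per seed; the measured shell thickness
reproduces the configured stage ratio; apical areas are smaller than basal
ones (inner surface); the spreading distance is the mean distance to the
five nearest cell centroids; relaxation trades tension energy for mild
elastic loading of the cells (evaluated on the normalized, unit-radius
sphere — see `docs/methods.md`).

The same pipeline runs from the shell:

```sh
organoidvm generate --n-seeds 400 --stage intermediate -o mesh.json
organoidvm relax mesh.json -o relaxed.json --trace trace.csv
organoidvm descriptors mesh relaxed.json -o descriptors.csv
organoidvm export-inp relaxed.json --plan maturation -o organoid.inp
organoidvm minisolve relaxed.json -o fields.csv --deformed deformed.json
organoidvm aggregate relaxed.json --fields fields.csv -o per_cell.csv
organoidvm run --stage immature -o run-immature/        # end to end
```

`descriptors labels` computes the same per-cell table from a segmented 3D
label image (cells + lumen label + background), so in-silico and imaged
organoids are measured with one code path.

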