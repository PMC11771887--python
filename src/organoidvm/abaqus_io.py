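"""Solver input-deck emission, neutral exports and result-table ingestion.

The deck writer emits a single keyword text file (.inp dialect) containing
the node table, typed element blocks, element/node sets named after the
material library, material blocks (elastic, density, expansion and specific
heat for the cortex, a single-term normalized shear-relaxation viscoelastic
record), surface definitions and one solver step per load-plan step.

Unit system: lengths in μm, moduli in MPa as printed; surface pressures are
converted Pa → MPa (× 1e-6) on write.  Mass density is passed through as
printed (its unit is ambiguous in the source table; quasi-static analyses
make it inert).

Results come back as a neutral CSV field table (one row per element:
``element_id, mises, e11, e22, e33, e12, e13, e23``, stress in MPa, strain
components as dimensionless tensor components), which is joined to the
element→cell map for per-cell aggregation.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DeckError, InvalidConfigurationError
from .femgen import (
    BLOCK_APICAL_CORTEX,
    BLOCK_BASAL_CORTEX,
    BLOCK_CYTOPLASM,
    BLOCK_LATERAL_CORTEX,
    LoadPlan,
    MaterialSpec,
    PrescribedDisplacement,
    SubcellularMesh,
    SurfacePressure,
    TemperatureLoad,
)

FIELD_TABLE_COLUMNS = ["element_id", "mises", "e11", "e22", "e33", "e12", "e13", "e23"]

PA_TO_MPA = 1e-6

CORTEX_BLOCKS = (BLOCK_APICAL_CORTEX, BLOCK_BASAL_CORTEX, BLOCK_LATERAL_CORTEX)


@dataclass
class DeckOptions:
    """Options controlling deck emission.

    ``cortex_element`` selects 3-node line trusses (T3D3T, default) or the
    3-node thermal shell variant (S3RT) for the cortex rings; both share the
    same ring geometry.  Steps containing temperature loads always use the
    coupled temperature-displacement procedure.
    """

    unit_system: str = "um-MPa"
    cortex_element: str = "T3D3T"
    shell_thickness_um: float = 0.1     # nominal membrane shell thickness
    truss_area_um2: float = 0.1         # nominal cortex cross-section
    write_viscoelastic: bool = True
    output_requests: tuple[str, ...] = ("S", "E", "U", "MISES")

    def __post_init__(self) -> None:
        if self.cortex_element not in ("T3D3T", "S3RT"):
            raise InvalidConfigurationError(
                f"cortex_element must be T3D3T or S3RT, got {self.cortex_element}")


# ---------------------------------------------------------------------------
# deck writing
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.9g}"


def write_inp(sub: SubcellularMesh, materials: list[MaterialSpec], plan: LoadPlan,
              options: DeckOptions | None = None, path=None) -> str:
    """Emit a solver-ready keyword deck; byte-identical for identical inputs.

    Raises :class:`DeckError` before writing anything if the plan references
    a region absent from the mesh.
    """
    options = options or DeckOptions()
    known_regions = (set(sub.surfaces) | set(sub.node_sets)
                     | {b.name for b in sub.blocks.values()})
    missing = plan.regions() - known_regions
    if missing:
        raise DeckError(f"plan references unknown regions {sorted(missing)}")
    mat_by_name = {m.name: m for m in materials}
    missing_mats = [b for b in sub.blocks if b not in mat_by_name]
    if missing_mats:
        raise DeckError(f"no material for element sets {missing_mats}")

    out = io.StringIO()
    w = out.write
    w("*HEADING\n")
    w("organoidvm subcellular organoid model\n")
    w(f"** unit system: {options.unit_system} (length um, stress MPa)\n")
    w("** pressures converted Pa -> MPa (x 1e-6) on write\n")
    w("** mass density passed through as printed; unit ambiguous in the source\n")
    w("** table, inert in quasi-static analyses\n")
    w("*NODE\n")
    for i, v in enumerate(sub.nodes, start=1):
        w(f"{i}, {_fmt(v[0])}, {_fmt(v[1])}, {_fmt(v[2])}\n")

    for name, blk in sub.blocks.items():
        etype = blk.elem_type
        if name in CORTEX_BLOCKS:
            etype = options.cortex_element
        w(f"*ELEMENT, TYPE={etype}, ELSET={name}\n")
        for eid, row in zip(blk.element_ids, blk.connectivity):
            w(f"{eid}, " + ", ".join(str(int(n) + 1) for n in row) + "\n")

    for name, nset in sorted(sub.node_sets.items()):
        w(f"*NSET, NSET={name}\n")
        ids = [str(int(n) + 1) for n in nset]
        for k in range(0, len(ids), 16):
            w(", ".join(ids[k:k + 16]) + "\n")

    for sname, mem_block in (("apical_surface", "Apical membrane"),
                             ("basal_surface", "Basal membrane")):
        if sname in sub.surfaces:
            w(f"*SURFACE, TYPE=ELEMENT, NAME={sname}\n")
            w(f"{mem_block}, SPOS\n")

    for name in sub.blocks:
        m = mat_by_name[name]
        w(f"*MATERIAL, NAME={name}\n")
        w("*ELASTIC\n")
        w(f"{_fmt(m.young_modulus)}, {_fmt(m.poisson_ratio)}\n")
        if m.mass_density is not None:
            w("*DENSITY\n")
            w(f"{_fmt(m.mass_density)},\n")
        if m.expansion is not None:
            w("*EXPANSION\n")
            w(f"{_fmt(m.expansion)},\n")
        if m.specific_heat is not None:
            w("*SPECIFIC HEAT\n")
            w(f"{_fmt(m.specific_heat)},\n")
        if options.write_viscoelastic and m.viscous_modulus is not None:
            # single-term normalized shear-relaxation pair: the printed
            # viscous modulus is the modulus ratio g1, the relaxation rate
            # the relaxation time tau1 (interpretation; see docs)
            w("*VISCOELASTIC, TIME=PRONY\n")
            w(f"{_fmt(m.viscous_modulus)}, 0., {_fmt(m.relaxation_rate)}\n")

    for name, blk in sub.blocks.items():
        if blk.elem_type in ("C3D10M", "C3D4"):
            w(f"*SOLID SECTION, ELSET={name}, MATERIAL={name}\n")
        elif blk.elem_type == "STRI65" or (
                name in CORTEX_BLOCKS and options.cortex_element == "S3RT"):
            w(f"*SHELL SECTION, ELSET={name}, MATERIAL={name}\n")
            w(f"{_fmt(options.shell_thickness_um)},\n")
        else:  # truss
            w(f"*SOLID SECTION, ELSET={name}, MATERIAL={name}\n")
            w(f"{_fmt(options.truss_area_um2)},\n")

    w("*INITIAL CONDITIONS, TYPE=TEMPERATURE\n")
    for name in CORTEX_BLOCKS:
        if name + " nodes" in sub.node_sets:
            w(f"{name} nodes, 0.\n")

    for step in plan.steps:
        has_temp = any(isinstance(ld, TemperatureLoad) for ld in step.loads)
        w(f"*STEP, NAME={step.name}, NLGEOM=NO\n")
        if has_temp:
            w("*COUPLED TEMPERATURE-DISPLACEMENT, STEADY STATE\n")
        else:
            w("*STATIC\n")
        w("1., 1.\n")
        pressures = [ld for ld in step.loads if isinstance(ld, SurfacePressure)]
        if pressures:
            w("*DSLOAD\n")
            for ld in pressures:
                # positive load value = pressure outward from the cell
                w(f"{ld.region}, P, {_fmt(ld.pascals * PA_TO_MPA)}\n")
        temps = [ld for ld in step.loads if isinstance(ld, TemperatureLoad)]
        if temps:
            w("*TEMPERATURE\n")
            for ld in temps:
                w(f"{ld.region} nodes, {_fmt(ld.value)}\n")
        disps = [ld for ld in step.loads if isinstance(ld, PrescribedDisplacement)]
        if disps:
            w("*BOUNDARY\n")
            for ld in disps:
                for node, u in sorted(ld.displacements.items()):
                    for axis in range(3):
                        w(f"{node + 1}, {axis + 1}, {axis + 1}, {_fmt(u[axis])}\n")
        w("*EL PRINT\n")
        w(", ".join(options.output_requests) + "\n")
        w("*END STEP\n")

    text = out.getvalue()
    if path is not None:
        with open(path, "w", newline="\n") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# deck reading (round-trip verification)
# ---------------------------------------------------------------------------

@dataclass
class DeckSummary:
    """Counts and load/material echo parsed back from a written deck."""

    n_nodes: int = 0
    element_counts: dict[str, int] = field(default_factory=dict)   # elset -> n
    element_types: dict[str, str] = field(default_factory=dict)    # elset -> type
    node_set_counts: dict[str, int] = field(default_factory=dict)
    surfaces: list[str] = field(default_factory=list)
    materials: dict[str, dict[str, float]] = field(default_factory=dict)
    steps: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def step_pressure_pa(self, step: int, region: str) -> float:
        """Pressure echo for one step/region, converted back to Pa."""
        for reg, mpa in self.steps[step]["pressures"]:
            if reg == region:
                return mpa / PA_TO_MPA
        raise KeyError(f"step {step} has no pressure on {region}")


_KNOWN_KEYWORDS = {
    "HEADING", "NODE", "ELEMENT", "NSET", "ELSET", "SURFACE", "MATERIAL",
    "ELASTIC", "DENSITY", "EXPANSION", "SPECIFIC HEAT", "VISCOELASTIC",
    "SOLID SECTION", "SHELL SECTION", "INITIAL CONDITIONS", "STEP", "STATIC",
    "COUPLED TEMPERATURE-DISPLACEMENT", "DSLOAD", "TEMPERATURE", "BOUNDARY",
    "EL PRINT", "END STEP",
}


def _parse_keyword(line: str) -> tuple[str, dict[str, str]]:
    parts = [p.strip() for p in line[1:].split(",")]
    kw = parts[0].upper()
    params = {}
    for p in parts[1:]:
        if "=" in p:
            k, v = p.split("=", 1)
            params[k.strip().upper()] = v.strip()
        else:
            params[p.upper()] = ""
    return kw, params


def read_deck_summary(path) -> DeckSummary:
    """Parse a generated deck back into counts and a load/material echo.

    Malformed data lines raise :class:`DeckError` with the line number;
    unknown keywords are collected as warnings, not failures.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    s = DeckSummary()
    mode = None
    current_elset = None
    current_material = None
    current_nset = None
    step = None
    for ln, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw, params = _parse_keyword(line)
            if kw not in _KNOWN_KEYWORDS:
                s.warnings.append(f"line {ln}: unknown keyword *{kw}")
                mode = None
                continue
            mode = kw
            if kw == "ELEMENT":
                current_elset = params.get("ELSET", "(anonymous)")
                s.element_counts.setdefault(current_elset, 0)
                s.element_types[current_elset] = params.get("TYPE", "?")
            elif kw == "NSET":
                current_nset = params.get("NSET", "(anonymous)")
                s.node_set_counts.setdefault(current_nset, 0)
            elif kw == "SURFACE":
                s.surfaces.append(params.get("NAME", "(anonymous)"))
            elif kw == "MATERIAL":
                current_material = params.get("NAME", "(anonymous)")
                s.materials[current_material] = {}
            elif kw == "STEP":
                step = {"name": params.get("NAME", f"step{len(s.steps) + 1}"),
                        "procedure": None, "pressures": [], "temperatures": [],
                        "boundary_rows": 0}
                s.steps.append(step)
            elif kw in ("STATIC", "COUPLED TEMPERATURE-DISPLACEMENT"):
                if step is not None:
                    step["procedure"] = kw
            continue
        # data line
        try:
            if mode == "NODE":
                fields = line.split(",")
                if len(fields) != 4:
                    raise ValueError("node line needs 4 fields")
                int(fields[0]); [float(x) for x in fields[1:]]
                s.n_nodes += 1
            elif mode == "ELEMENT":
                [int(x) for x in line.rstrip(",").split(",")]
                s.element_counts[current_elset] += 1
            elif mode == "NSET":
                s.node_set_counts[current_nset] += len(
                    [x for x in line.split(",") if x.strip()])
            elif mode == "ELASTIC":
                e, nu = [float(x) for x in line.rstrip(",").split(",")]
                s.materials[current_material]["young_modulus"] = e
                s.materials[current_material]["poisson_ratio"] = nu
            elif mode == "DENSITY":
                s.materials[current_material]["mass_density"] = float(line.rstrip(","))
            elif mode == "EXPANSION":
                s.materials[current_material]["expansion"] = float(line.rstrip(","))
            elif mode == "SPECIFIC HEAT":
                s.materials[current_material]["specific_heat"] = float(line.rstrip(","))
            elif mode == "VISCOELASTIC":
                g, k, tau = [float(x) for x in line.rstrip(",").split(",")]
                s.materials[current_material]["viscous_modulus"] = g
                s.materials[current_material]["relaxation_rate"] = tau
            elif mode == "DSLOAD":
                region, label, value = [x.strip() for x in line.split(",")]
                if label != "P":
                    raise ValueError(f"unsupported load label {label}")
                step["pressures"].append((region, float(value)))
            elif mode == "TEMPERATURE":
                region, value = line.rsplit(",", 1)
                step["temperatures"].append((region.strip(), float(value)))
            elif mode == "BOUNDARY":
                step["boundary_rows"] += 1
        except (ValueError, IndexError) as exc:
            raise DeckError(f"line {ln}: malformed data line ({exc}): {raw!r}") from exc
    return s


# ---------------------------------------------------------------------------
# field tables and per-cell aggregation
# ---------------------------------------------------------------------------

@dataclass
class FieldTable:
    """Validated per-element result table joined to the element→cell map."""

    data: pd.DataFrame   # FIELD_TABLE_COLUMNS + "cell_id"

    def __len__(self) -> int:
        return len(self.data)


def read_field_table(path, sub: SubcellularMesh) -> FieldTable:
    """Read a neutral CSV field table and join it to the element→cell map.

    Every row's element id must exist in the mesh (unknown or duplicated ids
    are errors) and every cytoplasm element must be present.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in FIELD_TABLE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DeckError(f"field table is missing columns {missing_cols}")
    if df["element_id"].duplicated().any():
        dup = df.loc[df["element_id"].duplicated(), "element_id"].iloc[0]
        raise DeckError(f"duplicated element id {int(dup)} in field table")
    if (df["mises"] < 0).any():
        raise DeckError("negative von Mises stress in field table")
    ecm = sub.element_cell_map()
    unknown = set(df["element_id"].astype(int)) - set(ecm)
    if unknown:
        raise DeckError(f"field table references unknown element ids "
                        f"{sorted(unknown)[:5]}")
    cyto_ids = set(int(e) for e in sub.blocks[BLOCK_CYTOPLASM].element_ids)
    absent = cyto_ids - set(df["element_id"].astype(int))
    if absent:
        raise DeckError(f"field table is missing cytoplasm elements "
                        f"{sorted(absent)[:5]} ({len(absent)} total)")
    out = df.copy()
    out["cell_id"] = out["element_id"].astype(int).map(ecm)
    return FieldTable(data=out)


def equivalent_strain(e: np.ndarray) -> np.ndarray:
    """Von-Mises-type scalar √(2/3 · e:e) of the deviatoric strain.

    ``e`` is (n, 6): tensor components e11, e22, e33, e12, e13, e23.
    """
    tr = e[:, 0] + e[:, 1] + e[:, 2]
    dev = e[:, :3] - tr[:, None] / 3.0
    ee = (dev ** 2).sum(axis=1) + 2.0 * (e[:, 3:] ** 2).sum(axis=1)
    return np.sqrt(2.0 / 3.0 * ee)


def per_cell_fields(table: FieldTable, sub: SubcellularMesh,
                    volume_weighted: bool = False) -> pd.DataFrame:
    """Mean von Mises stress (MPa) and mean equivalent strain per cell.

    The mean runs over each cell's cytoplasm elements and is unweighted by
    default; ``volume_weighted=True`` weights by linear-corner tetra volume.
    Cells without any element in the table get NaN.
    """
    cyto = sub.blocks[BLOCK_CYTOPLASM]
    df = table.data[table.data["element_id"].isin(cyto.element_ids)].copy()
    df["eq_strain"] = equivalent_strain(
        df[["e11", "e22", "e33", "e12", "e13", "e23"]].to_numpy(float))
    if volume_weighted:
        p = sub.nodes[cyto.connectivity[:, :4]]
        vols = np.einsum("ij,ij->i", p[:, 1] - p[:, 0],
                         np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0])) / 6.0
        volmap = dict(zip((int(e) for e in cyto.element_ids), vols))
        df["_w"] = df["element_id"].astype(int).map(volmap)
        grouped = df.groupby("cell_id").apply(
            lambda g: pd.Series({
                "mean_mises_mpa": np.average(g["mises"], weights=g["_w"]),
                "mean_equivalent_strain": np.average(g["eq_strain"], weights=g["_w"]),
            }), include_groups=False)
        out = grouped.reset_index()
    else:
        out = (df.groupby("cell_id")[["mises", "eq_strain"]].mean()
               .rename(columns={"mises": "mean_mises_mpa",
                                "eq_strain": "mean_equivalent_strain"})
               .reset_index())
    n_cells = sub.source.n_cells if sub.source is not None else out["cell_id"].max() + 1
    full = pd.DataFrame({"cell_id": np.arange(n_cells)})
    out = full.merge(out, on="cell_id", how="left")
    if out[["mean_mises_mpa"]].isna().any().any():
        warnings.warn("some cells have no field-table elements; reported as NaN",
                      stacklevel=2)
    return out


def write_field_table(path, element_ids, mises, strains) -> None:
    """Write the neutral CSV field-table dialect."""
    df = pd.DataFrame({"element_id": np.asarray(element_ids, dtype=int),
                       "mises": mises})
    strains = np.asarray(strains)
    for k, col in enumerate(["e11", "e22", "e33", "e12", "e13", "e23"]):
        df[col] = strains[:, k]
    df.to_csv(path, index=False)
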