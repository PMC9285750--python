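"""Configuration schema, format readers/writers and report generation.

Meshes round-trip through Gmsh MSH 2.2 ASCII (boundary facets stored as
lower-dimensional elements carrying their physical tag); fields export to
ASCII VTU.  Case configurations are YAML/JSON with explicit units:
pressures enter in mmHg (mean, or systolic/diastolic pair combined by the
mean-arterial-pressure rule) and are converted to dyn/cm^2 at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import meshing
from .lumped import mean_arterial_pressure
from .measurements import MeasurementSet
from .meshing import VesselMesh
from .units import MMHG_TO_DYN_CM2

SCHEMA_VERSION = "1"

_GMSH_TYPE = {1: 1, 2: 2, 4: 4}     # line, triangle, tetrahedron
_CELL_TYPE_BY_DIM = {2: 2, 3: 4}    # mesh dim -> gmsh cell type
_FACET_TYPE_BY_DIM = {2: 1, 3: 2}   # mesh dim -> gmsh facet type


# ---------------------------------------------------------------------------
# Gmsh MSH 2.2
# ---------------------------------------------------------------------------

def write_msh(mesh: VesselMesh, path) -> None:
    """Write a VesselMesh as Gmsh MSH 2.2 ASCII with tagged boundary facets."""
    path = Path(path)
    d = mesh.dim
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$Nodes",
             str(mesh.n_vertices)]
    for i, v in enumerate(mesh.vertices, start=1):
        xyz = list(v) + [0.0] * (3 - d)
        lines.append(f"{i} {xyz[0]:.16g} {xyz[1]:.16g} {xyz[2]:.16g}")
    lines += ["$EndNodes", "$Elements",
              str(mesh.n_cells + mesh.facets.shape[0])]
    eid = 1
    ftype = _FACET_TYPE_BY_DIM[d]
    for f, tag in zip(mesh.facets, mesh.facet_tags):
        conn = " ".join(str(v + 1) for v in f)
        lines.append(f"{eid} {ftype} 2 {tag} {tag} {conn}")
        eid += 1
    ctype = _CELL_TYPE_BY_DIM[d]
    for c in mesh.cells:
        conn = " ".join(str(v + 1) for v in c)
        lines.append(f"{eid} {ctype} 2 0 0 {conn}")
        eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_msh(path) -> VesselMesh:
    """Read a VesselMesh written by :func:`write_msh`."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)

    def until(marker):
        for line in it:
            if line.strip() == marker:
                return
        raise ValueError(f"malformed MSH file: missing {marker}")

    until("$Nodes")
    n_nodes = int(next(it))
    verts3 = np.empty((n_nodes, 3))
    for k in range(n_nodes):
        parts = next(it).split()
        verts3[k] = [float(p) for p in parts[1:4]]
    until("$EndNodes")
    until("$Elements")
    n_elem = int(next(it))
    cells, facets, tags = [], [], []
    for _ in range(n_elem):
        parts = next(it).split()
        etype = int(parts[1])
        ntags = int(parts[2])
        conn = [int(p) - 1 for p in parts[3 + ntags:]]
        phys = int(parts[3]) if ntags else 0
        if etype in (1, 2) and phys != 0:
            facets.append(conn)
            tags.append(phys)
        elif etype in (2, 4) and phys == 0:
            cells.append(conn)
    cells = np.asarray(cells, dtype=np.int64)
    dim = cells.shape[1] - 1
    verts = verts3[:, :dim]
    facets = np.asarray(facets, dtype=np.int64)
    # recover facet->cell adjacency
    bf, owners = meshing._boundary_facets(cells, dim)
    lookup = {tuple(sorted(f)): o for f, o in zip(bf.tolist(), owners.tolist())}
    fcells = np.array([lookup[tuple(sorted(f))] for f in facets.tolist()],
                      dtype=np.int64)
    mesh = VesselMesh(verts, cells, facets, np.asarray(tags, dtype=np.int64),
                      fcells)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# VTU (ASCII) field export
# ---------------------------------------------------------------------------

_VTK_CELL = {2: 5, 3: 10}  # triangle, tetra


def write_vtu(mesh: VesselMesh, path, point_data: dict | None = None) -> None:
    """Write the mesh and vertex-based fields as ASCII VTU.

    ``point_data`` maps array names to (n_vertices,) or (n_vertices, dim)
    arrays; P2 velocity fields should be passed restricted to vertices
    (``field[:mesh.n_vertices]``).
    """
    path = Path(path)
    nv, nc, d = mesh.n_vertices, mesh.n_cells, mesh.dim
    pts = np.column_stack([mesh.vertices] + [np.zeros(nv)] * (3 - d))
    out = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{nv}" NumberOfCells="{nc}">',
        '<Points>',
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{x:.12g}" for x in p) for p in pts),
        '</DataArray>', '</Points>', '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        "\n".join(" ".join(str(v) for v in c) for c in mesh.cells),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(str((i + 1) * (d + 1)) for i in range(nc)),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(str(_VTK_CELL[d]) for _ in range(nc)),
        '</DataArray>', '</Cells>',
    ]
    if point_data:
        out.append('<PointData>')
        for name, arr in point_data.items():
            arr = np.asarray(arr)[:nv]
            if arr.ndim == 1:
                ncomp, flat = 1, arr
            else:
                pad = np.column_stack([arr] + [np.zeros(nv)] * (3 - arr.shape[1]))
                ncomp, flat = 3, pad.ravel()
            out.append(f'<DataArray type="Float64" Name="{name}" '
                       f'NumberOfComponents="{ncomp}" format="ascii">')
            out.append(" ".join(f"{x:.12g}" for x in np.ravel(flat)))
            out.append('</DataArray>')
        out.append('</PointData>')
    out += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# case configuration
# ---------------------------------------------------------------------------

@dataclass
class CaseConfig:
    """Validated case description (paths, measurements, solver settings)."""

    mesh_path: str
    measurements: MeasurementSet
    viscosity: float = 0.04
    seed: int = 0
    max_iterations: int = 50
    tolerance: float = 1e-8
    control_inlet: bool = False
    output_dir: str = "."
    labels: list = dc_field(default_factory=list)
    schema_version: str = SCHEMA_VERSION


def load_case(path) -> tuple[CaseConfig, VesselMesh, MeasurementSet]:
    """Load and validate a YAML/JSON case file.

    The measurement block must provide either ``mean_pressure_mmhg`` or the
    ``systolic_mmhg``/``diastolic_mmhg`` pair; flows are keyed by outlet
    tag and every tag must exist in the mesh.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    errors = []
    if "schema_version" not in raw:
        errors.append("missing schema_version")
    mb = raw.get("measurements", {})
    if "mean_pressure_mmhg" in mb:
        p_mmhg = float(mb["mean_pressure_mmhg"])
    elif "systolic_mmhg" in mb and "diastolic_mmhg" in mb:
        p_mmhg = mean_arterial_pressure(float(mb["systolic_mmhg"]),
                                        float(mb["diastolic_mmhg"]))
    else:
        errors.append("measurements need mean_pressure_mmhg or "
                      "systolic_mmhg + diastolic_mmhg")
        p_mmhg = None
    mesh_path = raw.get("mesh")
    if mesh_path is None:
        errors.append("missing mesh path")
    if errors:
        raise ValueError("invalid case file: " + "; ".join(errors))
    mesh_file = Path(mesh_path)
    if not mesh_file.is_absolute():
        mesh_file = path.parent / mesh_file
    mesh = read_msh(mesh_file)

    flows = mb.get("outlet_flows_cm3_s", {})
    flows = {int(k): float(v) for k, v in flows.items()}
    missing = [t for t in flows if t not in mesh.outlet_tags]
    if missing:
        raise ValueError(f"outlet tags absent from mesh: {missing}")
    absent = [t for t in mesh.outlet_tags if t not in flows]
    if absent:
        raise ValueError(f"no measured flow for outlet tags: {absent}")
    solver = raw.get("solver", {})
    weights = raw.get("weights", {})
    meas = MeasurementSet(
        p_d=p_mmhg * MMHG_TO_DYN_CM2,
        Q_in=float(mb["inlet_flow_cm3_s"]),
        Q_out=np.array([flows[t] for t in mesh.outlet_tags]),
        pressure_section=int(mb.get("pressure_section", meshing.INLET)),
        alpha_p=float(weights.get("alpha_p", 1.0)),
        alpha_out=np.asarray(weights.get("alpha_out", 1.0), dtype=float),
        alpha_in=float(weights.get("alpha_in", 1.0)),
    )
    cfg = CaseConfig(
        mesh_path=str(mesh_file), measurements=meas,
        viscosity=float(solver.get("viscosity", 0.04)),
        seed=int(solver.get("seed", 0)),
        max_iterations=int(solver.get("max_iterations", 50)),
        tolerance=float(solver.get("tolerance", 1e-8)),
        control_inlet=bool(raw.get("control_inlet", False)),
        output_dir=str(raw.get("output_dir", ".")),
        labels=list(raw.get("labels", [])),
        schema_version=str(raw["schema_version"]))
    return cfg, mesh, meas


def save_case(cfg: CaseConfig, path) -> None:
    """Write a case file that :func:`load_case` reads back identically."""
    meas = cfg.measurements
    doc = {
        "schema_version": cfg.schema_version,
        "mesh": cfg.mesh_path,
        "measurements": {
            "mean_pressure_mmhg": meas.p_d / MMHG_TO_DYN_CM2,
            "inlet_flow_cm3_s": meas.Q_in,
            "outlet_flows_cm3_s": {
                # tags keyed as strings for YAML friendliness
                str(10 + i + 1): float(q) for i, q in enumerate(meas.Q_out)},
            "pressure_section": meas.pressure_section,
        },
        "weights": {"alpha_p": meas.alpha_p,
                    "alpha_out": meas.alpha_out.tolist(),
                    "alpha_in": meas.alpha_in},
        "solver": {"viscosity": cfg.viscosity, "seed": cfg.seed,
                   "max_iterations": cfg.max_iterations,
                   "tolerance": cfg.tolerance},
        "control_inlet": cfg.control_inlet,
        "output_dir": cfg.output_dir,
        "labels": cfg.labels,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(results: dict, path_stem, labels: list | None = None) -> None:
    """Write per-method calibration results as CSV + JSON.

    ``results`` maps method name -> dict with keys ``outlet_tags``,
    ``R`` (dyn.s/cm^5), ``Q_pred`` and ``Q_meas`` (cm^3/s).  Percentage
    errors are 100*(pred-meas)/meas to one decimal (negative means
    under-prediction); rows with zero measured flow carry "NA".
    """
    import warnings as _w
    rows = []
    for method, r in results.items():
        tags = r["outlet_tags"]
        lab = labels if labels else [str(t) for t in tags]
        for i, tag in enumerate(tags):
            meas = r["Q_meas"][i]
            pred = r["Q_pred"][i]
            if meas == 0:
                pct = "NA"
                _w.warn(f"zero measured flow for outlet {tag}; "
                        "error reported as NA")
            else:
                pct = round(100.0 * (pred - meas) / meas, 1)
            rows.append({
                "method": method, "outlet": tag, "label": lab[i],
                "R_dyn_s_cm5": float(r["R"][i]),
                "Q_pred_cm3_s": float(pred), "Q_meas_cm3_s": float(meas),
                "pct_error": pct})
    df = pd.DataFrame(rows)
    stem = Path(path_stem)
    df.to_csv(stem.with_suffix(".csv"), index=False,
              float_format="%.12g")
    stem.with_suffix(".json").write_text(
        json.dumps(rows, indent=2, default=float) + "\n")


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------

def read_waveform_csv(path):
    """Read a waveform CSV with columns t_s, q_cm3_s."""
    from .windkessel import FlowWaveform
    df = pd.read_csv(path)
    return FlowWaveform(df["t_s"].to_numpy(), df["q_cm3_s"].to_numpy())


def write_waveform_csv(waveform, path) -> None:
    pd.DataFrame({"t_s": waveform.times,
                  "q_cm3_s": waveform.values}).to_csv(path, index=False)
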