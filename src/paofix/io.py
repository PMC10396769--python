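"""Text-format I/O: gait CSV/JSON, INP-subset meshes, legacy VTK results.

Meshes travel as an Abaqus-INP subset (*NODE, *ELEMENT TYPE=C3D4, *ELSET,
*NSET keyword blocks, 1-based ids); solved fields as legacy ASCII VTK
unstructured grids (point displacements, cell von Mises); gait trials as a
CSV of the time series plus a JSON sidecar for mass, events and seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fe_solver import FieldResult, TetMesh
from .gait_processing import GaitCycleCurves, GaitTrial

GAIT_COLUMNS = [
    "time_s",
    "angle_sagittal_deg", "angle_frontal_deg", "angle_transverse_deg",
    "grf_x_N", "grf_y_N", "grf_z_N",
    "grm_x_Nm", "grm_y_Nm", "grm_z_Nm",
]


# ---------------------------------------------------------------------------
# Gait trials
# ---------------------------------------------------------------------------

def write_gait_trial(trial: GaitTrial, csv_path) -> None:
    """Trial time series as CSV + JSON sidecar (<name>.json)."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(
        np.column_stack([trial.time, trial.angles_deg, trial.grf_N, trial.grm_Nm]),
        columns=GAIT_COLUMNS,
    )
    df.to_csv(csv_path, index=False)
    sidecar = {
        "body_mass_kg": trial.body_mass_kg,
        "events": {k: list(map(float, v)) for k, v in trial.events.items()},
        "meta": _jsonable(trial.meta),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_gait_trial(csv_path) -> GaitTrial:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    missing = [c for c in GAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gait CSV lacks columns: {missing}")
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    return GaitTrial(
        time=df["time_s"].to_numpy(),
        angles_deg=df[GAIT_COLUMNS[1:4]].to_numpy(),
        grf_N=df[GAIT_COLUMNS[4:7]].to_numpy(),
        grm_Nm=df[GAIT_COLUMNS[7:10]].to_numpy(),
        body_mass_kg=float(sidecar["body_mass_kg"]),
        events=sidecar.get("events", {}),
        meta=sidecar.get("meta", {}),
    )


def write_cycle_curves(curves: GaitCycleCurves, csv_path) -> None:
    df = pd.DataFrame(
        np.column_stack([curves.percent, curves.angles_deg, curves.grf_N, curves.grm_Nm]),
        columns=["percent"] + GAIT_COLUMNS[1:],
    )
    df.to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# INP-subset meshes
# ---------------------------------------------------------------------------

def write_inp(mesh: TetMesh, path) -> None:
    """Mesh + named sets as an Abaqus-INP text subset (1-based ids)."""
    lines = ["*HEADING", "paofix tet4 mesh", "*NODE"]
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")
    lines.append("*ELEMENT, TYPE=C3D4")
    for i, el in enumerate(mesh.elements, start=1):
        lines.append(f"{i}, {el[0] + 1}, {el[1] + 1}, {el[2] + 1}, {el[3] + 1}")
    for name, ids in mesh.element_sets.items():
        lines.append(f"*ELSET, ELSET={name}")
        lines.extend(_id_lines(np.asarray(ids) + 1))
    for name, ids in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={name}")
        lines.extend(_id_lines(np.asarray(ids) + 1))
    Path(path).write_text("\n".join(lines) + "\n")


def _id_lines(ids: np.ndarray, per_line: int = 16) -> list[str]:
    out = []
    for start in range(0, len(ids), per_line):
        out.append(", ".join(str(int(i)) for i in ids[start:start + per_line]))
    return out


def read_inp(path) -> TetMesh:
    """Read the INP subset written by :func:`write_inp`.

    Recognised keywords: *NODE, *ELEMENT (TYPE=C3D4), *ELSET, *NSET;
    everything else is skipped.
    """
    nodes, elements = [], []
    node_sets: dict[str, list[int]] = {}
    element_sets: dict[str, list[int]] = {}
    mode, current = None, None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("**"):
            continue
        if line.startswith("*"):
            keyword = line.split(",")[0].upper()
            params = dict(
                p.split("=", 1) for p in
                (s.strip() for s in line.split(",")[1:]) if "=" in p
            )
            params = {k.upper(): v for k, v in params.items()}
            if keyword == "*NODE":
                mode = "node"
            elif keyword == "*ELEMENT":
                if params.get("TYPE", "C3D4").upper() != "C3D4":
                    raise ValueError(f"unsupported element type {params.get('TYPE')}")
                mode = "element"
            elif keyword == "*ELSET":
                mode, current = "elset", params.get("ELSET", "unnamed")
                element_sets.setdefault(current, [])
            elif keyword == "*NSET":
                mode, current = "nset", params.get("NSET", "unnamed")
                node_sets.setdefault(current, [])
            else:
                mode = None
            continue
        parts = [p for p in (s.strip() for s in line.split(",")) if p]
        if mode == "node":
            nodes.append([float(v) for v in parts[1:4]])
        elif mode == "element":
            elements.append([int(v) - 1 for v in parts[1:5]])
        elif mode == "elset":
            element_sets[current].extend(int(v) - 1 for v in parts)
        elif mode == "nset":
            node_sets[current].extend(int(v) - 1 for v in parts)
    return TetMesh(
        nodes=np.asarray(nodes, dtype=float),
        elements=np.asarray(elements, dtype=int),
        node_sets={k: np.asarray(v, dtype=int) for k, v in node_sets.items()},
        element_sets={k: np.asarray(v, dtype=int) for k, v in element_sets.items()},
    )


# ---------------------------------------------------------------------------
# Legacy VTK results
# ---------------------------------------------------------------------------

def write_vtk(mesh: TetMesh, path, result: FieldResult | None = None,
              cell_flags: np.ndarray | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with optional solved fields."""
    n_nodes, n_elem = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "paofix results",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n_nodes} double",
    ]
    lines.extend(f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes)
    lines.append(f"CELLS {n_elem} {5 * n_elem}")
    lines.extend(f"4 {a} {b} {c} {d}" for a, b, c, d in mesh.elements)
    lines.append(f"CELL_TYPES {n_elem}")
    lines.extend(["10"] * n_elem)
    if result is not None:
        lines.append(f"POINT_DATA {n_nodes}")
        lines.append("VECTORS displacement double")
        lines.extend(f"{u:.9g} {v:.9g} {w:.9g}" for u, v, w in result.displacements)
        lines.append(f"CELL_DATA {n_elem}")
        lines.append("SCALARS von_mises double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.9g}" for v in result.von_mises)
        if cell_flags is not None:
            lines.append("SCALARS failed int 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(str(int(v)) for v in cell_flags)
    elif cell_flags is not None:
        lines.append(f"CELL_DATA {n_elem}")
        lines.append("SCALARS failed int 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(str(int(v)) for v in cell_flags)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1, sort_keys=True))
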