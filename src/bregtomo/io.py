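"""Plain-text file I/O: legacy VTK, TetGen node/ele pairs, CSV, JSON.

Meshes and nodal fields travel as legacy ASCII VTK unstructured grids
(cell type 10 = tetrahedron), with region labels in cell data "region"
and nodal fields (source vectors, reconstructions) as point data.
Floats are written with 17 significant digits so write -> read -> write
round-trips byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import TetMesh

_F = "%.17g"


def write_vtk(path, mesh: TetMesh, point_data: dict | None = None,
              title: str = "bregtomo mesh") -> None:
    """Write a mesh (+ optional nodal scalar fields) as legacy ASCII VTK."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {mesh.n_nodes} double"]
    lines += [" ".join(_F % v for v in p) for p in mesh.nodes]
    lines.append(f"CELLS {mesh.n_tets} {5 * mesh.n_tets}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in mesh.tets]
    lines.append(f"CELL_TYPES {mesh.n_tets}")
    lines += ["10"] * mesh.n_tets
    lines.append(f"CELL_DATA {mesh.n_tets}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(r)) for r in mesh.region]
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.shape != (mesh.n_nodes,):
                raise ValueError(
                    f"point data {name!r} has shape {values.shape}, "
                    f"expected ({mesh.n_nodes},)")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines += [_F % v for v in values]
    path.write_text("\n".join(lines) + "\n")


def read_vtk(path) -> tuple[TetMesh, dict]:
    """Read a legacy ASCII VTK unstructured grid of tetrahedra."""
    tok = Path(path).read_text().split("\n")
    # strip the 4-line header, then token-scan
    words = " ".join(tok[4:]).split()
    i = 0

    def expect(kw):
        nonlocal i
        if words[i].upper() != kw:
            raise ValueError(f"{path}: expected {kw}, found {words[i]!r}")
        i += 1

    expect("POINTS")
    n = int(words[i]); i += 2  # count, dtype
    nodes = np.array(words[i:i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("CELLS")
    t = int(words[i]); total = int(words[i + 1]); i += 2
    raw = np.array(words[i:i + total], dtype=np.int64)
    i += total
    if not np.all(raw.reshape(t, 5)[:, 0] == 4):
        raise ValueError(f"{path}: non-tetrahedral cell present")
    tets = raw.reshape(t, 5)[:, 1:]
    expect("CELL_TYPES")
    i += 1 + t  # count + types
    region = None
    point_data: dict = {}
    while i < len(words):
        kw = words[i].upper()
        if kw == "CELL_DATA":
            i += 2
        elif kw == "POINT_DATA":
            i += 2
        elif kw == "SCALARS":
            name, dtype = words[i + 1], words[i + 2]
            i += 4 if words[i + 3].isdigit() else 3
            if words[i].upper() == "LOOKUP_TABLE":
                i += 2
            count = t if name == "region" else n
            vals = np.array(words[i:i + count],
                            dtype=np.int64 if dtype == "int" else float)
            i += count
            if name == "region":
                region = vals
            else:
                point_data[name] = vals
        else:
            raise ValueError(f"{path}: unsupported VTK section {words[i]!r}")
    mesh = TetMesh(nodes=nodes, tets=tets, region=region)
    return mesh, point_data


def write_tetgen(prefix, mesh: TetMesh) -> None:
    """Write a TetGen-style .node/.ele pair (region as element attribute)."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".node"), "w") as fh:
        fh.write(f"{mesh.n_nodes} 3 0 0\n")
        for k, p in enumerate(mesh.nodes):
            fh.write(f"{k} " + " ".join(_F % v for v in p) + "\n")
    with open(prefix.with_suffix(".ele"), "w") as fh:
        fh.write(f"{mesh.n_tets} 4 1\n")
        for k, (t, r) in enumerate(zip(mesh.tets, mesh.region)):
            fh.write(f"{k} {t[0]} {t[1]} {t[2]} {t[3]} {int(r)}\n")


def read_tetgen(prefix) -> TetMesh:
    """Read a TetGen-style .node/.ele pair written by :func:`write_tetgen`."""
    prefix = Path(prefix)
    node_lines = [ln.split() for ln in
                  prefix.with_suffix(".node").read_text().splitlines()
                  if ln.strip() and not ln.startswith("#")]
    n = int(node_lines[0][0])
    nodes = np.array([ln[1:4] for ln in node_lines[1:n + 1]], dtype=float)
    ele_lines = [ln.split() for ln in
                 prefix.with_suffix(".ele").read_text().splitlines()
                 if ln.strip() and not ln.startswith("#")]
    t = int(ele_lines[0][0])
    has_attr = int(ele_lines[0][2]) > 0
    tets = np.array([ln[1:5] for ln in ele_lines[1:t + 1]], dtype=np.int64)
    region = (np.array([ln[5] for ln in ele_lines[1:t + 1]], dtype=np.int64)
              if has_attr else None)
    return TetMesh(nodes=nodes, tets=tets, region=region)


def write_measurements_csv(path, A, measurements) -> None:
    """Measurements as CSV: excitation_id, detector_node, x, y, z, value."""
    rows = [{"excitation_id": e, "detector_node": d, "value": v}
            for (e, d), v in zip(A.row_meta, measurements.values)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_F)


def write_measurements_csv_with_coords(path, mesh: TetMesh, A,
                                       measurements) -> None:
    rows = [{"excitation_id": e, "detector_node": d,
             "x": mesh.nodes[d, 0], "y": mesh.nodes[d, 1],
             "z": mesh.nodes[d, 2], "value": v}
            for (e, d), v in zip(A.row_meta, measurements.values)]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_F)


def read_measurements_csv(path) -> tuple[list, np.ndarray]:
    """Return (row_meta, values) from a measurement CSV."""
    df = pd.read_csv(path, float_precision="round_trip")
    meta = [(int(e), int(d)) for e, d in
            zip(df["excitation_id"], df["detector_node"])]
    return meta, df["value"].to_numpy(dtype=float)


def save_sensitivity(prefix, A) -> None:
    """Dense matrix as .npy plus a JSON sidecar with the metadata."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), A.entries)
    sidecar = {
        "row_meta": [[int(e), int(d)] for e, d in A.row_meta],
        "col_nodes": [int(j) for j in A.col_nodes],
        "n_mesh_nodes": int(A.n_mesh_nodes),
        "channel": A.channel,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_sensitivity(prefix, mesh: TetMesh):
    from .sensitivity import SensitivityMatrix
    prefix = Path(prefix)
    entries = np.load(prefix.with_suffix(".npy"))
    side = json.loads(prefix.with_suffix(".json").read_text())
    col_nodes = np.array(side["col_nodes"], dtype=np.int64)
    return SensitivityMatrix(
        entries=entries,
        row_meta=[tuple(rm) for rm in side["row_meta"]],
        col_nodes=col_nodes, col_coords=mesh.nodes[col_nodes],
        n_mesh_nodes=side["n_mesh_nodes"], channel=side["channel"])


def write_run_record(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_run_record(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
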