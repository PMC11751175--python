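"""File I/O: legacy ASCII VTK for meshes and fields, YAML configs, CSV/JSON.

The VTK writer emits version-3.0 legacy unstructured grids (tetrahedra, cell
type 10) with optional per-cell and per-vertex data, plus a companion
POLYDATA surface file carrying boundary-patch ids.  The reader understands
the subset this package writes (round-trip fidelity is tested).
"""

from __future__ import annotations

import json

import numpy as np

__all__ = [
    "write_vtk_unstructured",
    "read_vtk_unstructured",
    "write_vtk_surface",
    "save_yaml",
    "load_yaml",
    "save_json",
]

SCHEMA_VERSION = 1


def _write_data_arrays(fh, data: dict, n: int, kind: str):
    if not data:
        return
    fh.write(f"{kind} {n}\n")
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            dtype = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fh.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
            fmt = "%d" if dtype == "int" else "%.17g"
            fh.write("\n".join(fmt % v for v in arr) + "\n")
        else:
            fh.write(f"VECTORS {name} double\n")
            for row in arr:
                fh.write(" ".join("%.17g" % v for v in row) + "\n")


def write_vtk_unstructured(path, vertices, cells, cell_data=None, point_data=None):
    vertices = np.asarray(vertices, float)
    cells = np.asarray(cells)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmvstim mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(vertices)} double\n")
        for p in vertices:
            fh.write("%.17g %.17g %.17g\n" % tuple(p))
        fh.write(f"CELLS {len(cells)} {len(cells) * 5}\n")
        for c in cells:
            fh.write("4 %d %d %d %d\n" % tuple(c))
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.write("\n".join(["10"] * len(cells)) + "\n")
        _write_data_arrays(fh, cell_data or {}, len(cells), "CELL_DATA")
        _write_data_arrays(fh, point_data or {}, len(vertices), "POINT_DATA")


def write_vtk_surface(path, vertices, faces, face_data=None):
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmvstim surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(vertices)} double\n")
        for p in vertices:
            fh.write("%.17g %.17g %.17g\n" % tuple(p))
        fh.write(f"POLYGONS {len(faces)} {len(faces) * 4}\n")
        for f in faces:
            fh.write("3 %d %d %d\n" % tuple(f))
        _write_data_arrays(fh, face_data or {}, len(faces), "CELL_DATA")


def read_vtk_unstructured(path):
    """Read a legacy ASCII tet mesh written by this package.

    Returns (vertices, cells, cell_data, point_data).
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    i = 0

    def next_line():
        nonlocal i
        while i < len(tokens) and not tokens[i].strip():
            i += 1
        if i >= len(tokens):
            return ""
        line = tokens[i]
        i += 1
        return line

    verts = cells = None
    cell_data: dict = {}
    point_data: dict = {}
    current = None
    while i < len(tokens):
        line = next_line() if i < len(tokens) else ""
        parts = line.split()
        if not parts:
            continue
        key = parts[0].upper()
        if key == "POINTS":
            n = int(parts[1])
            rows = [next_line().split() for _ in range(n)]
            verts = np.array(rows, dtype=float)
        elif key == "CELLS":
            n = int(parts[1])
            rows = [next_line().split()[1:] for _ in range(n)]
            cells = np.array(rows, dtype=np.int64)
        elif key == "CELL_TYPES":
            n = int(parts[1])
            for _ in range(n):
                next_line()
        elif key == "CELL_DATA":
            current = cell_data
        elif key == "POINT_DATA":
            current = point_data
        elif key == "SCALARS" and current is not None:
            name, dtype = parts[1], parts[2]
            next_line()  # LOOKUP_TABLE
            n = len(cells) if current is cell_data else len(verts)
            rows = [next_line() for _ in range(n)]
            current[name] = np.array(rows, dtype=int if dtype == "int" else float)
        elif key == "VECTORS" and current is not None:
            name = parts[1]
            n = len(cells) if current is cell_data else len(verts)
            rows = [next_line().split() for _ in range(n)]
            current[name] = np.array(rows, dtype=float)
    return verts, cells, cell_data, point_data


def save_yaml(obj: dict, path):
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def load_yaml(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def save_json(obj: dict, path):
    payload = {"schema_version": SCHEMA_VERSION}
    payload.update(_to_jsonable(obj))
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
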