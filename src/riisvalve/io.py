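"""Plain-text mesh and field I/O: legacy ASCII VTK plus CSV diagnostics.

Writers use ``%.17g`` formatting so round-tripping a double through the file
reproduces it bitwise.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np


def _fmt(a: np.ndarray) -> str:
    return "\n".join(" ".join(f"{x:.17g}" for x in row) for row in np.atleast_2d(a))


def write_vtk_polydata(path, vertices: np.ndarray, faces: np.ndarray) -> None:
    """Write a triangulated surface as legacy ASCII VTK POLYDATA."""
    vertices = np.asarray(vertices, dtype=float)
    faces = np.asarray(faces, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "riisvalve surface",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(vertices)} double",
        _fmt(vertices),
        f"POLYGONS {len(faces)} {4 * len(faces)}",
        "\n".join("3 " + " ".join(str(i) for i in f) for f in faces),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_unstructured(path, nodes: np.ndarray, cells: np.ndarray,
                           point_data: dict | None = None) -> None:
    """Write a tetrahedral mesh (+ nodal scalar/vector fields) as legacy ASCII VTK."""
    nodes = np.asarray(nodes, dtype=float)
    cells = np.asarray(cells, dtype=np.int64)
    lines = [
        "# vtk DataFile Version 3.0",
        "riisvalve volume",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
        _fmt(nodes),
        f"CELLS {len(cells)} {5 * len(cells)}",
        "\n".join("4 " + " ".join(str(i) for i in c) for c in cells),
        f"CELL_TYPES {len(cells)}",
        "\n".join(["10"] * len(cells)),
    ]
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, values in point_data.items():
            values = np.asarray(values, dtype=float)
            if values.ndim == 1:
                lines += [f"SCALARS {name} double 1", "LOOKUP_TABLE default",
                          "\n".join(f"{x:.17g}" for x in values)]
            else:
                lines += [f"VECTORS {name} double", _fmt(values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk_unstructured(path):
    """Read back a legacy ASCII VTK unstructured grid written by this module.

    Returns (nodes, cells, point_data).
    """
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    nodes = cells = None
    point_data: dict[str, np.ndarray] = {}
    n_points = 0
    line = next(it, None)
    while line is not None:
        parts = line.split()
        if parts and parts[0] == "POINTS":
            n_points = int(parts[1])
            vals = []
            while len(vals) < 3 * n_points:
                vals += next(it).split()
            nodes = np.array(vals, dtype=float).reshape(n_points, 3)
        elif parts and parts[0] == "CELLS":
            n_cells = int(parts[1])
            vals = []
            while len(vals) < 5 * n_cells:
                vals += next(it).split()
            arr = np.array(vals, dtype=np.int64).reshape(n_cells, 5)
            cells = arr[:, 1:]
        elif parts and parts[0] == "SCALARS":
            name = parts[1]
            next(it)  # LOOKUP_TABLE
            vals = []
            while len(vals) < n_points:
                vals += next(it).split()
            point_data[name] = np.array(vals, dtype=float)
        elif parts and parts[0] == "VECTORS":
            name = parts[1]
            vals = []
            while len(vals) < 3 * n_points:
                vals += next(it).split()
            point_data[name] = np.array(vals, dtype=float).reshape(n_points, 3)
        line = next(it, None)
    return nodes, cells, point_data


def write_diagnostics_csv(path, times, v_max, delta_p) -> None:
    """Write the (t, v_max, delta_p) diagnostics series as CSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["t_s", "v_max_m_per_s", "delta_p_mmHg"])
        for row in zip(times, v_max, delta_p):
            w.writerow([f"{x:.17g}" for x in row])


def read_diagnostics_csv(path):
    data = np.genfromtxt(path, delimiter=",", skip_header=1)
    data = np.atleast_2d(data)
    return data[:, 0], data[:, 1], data[:, 2]
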