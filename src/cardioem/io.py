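"""Plain-text interchange: legacy-VTK meshes and tabular traces.

Meshes are written as ASCII legacy VTK unstructured grids (tetrahedra plus
integer/float point-data fields), readable by ParaView and by this module.
"""

from __future__ import annotations

import numpy as np

from .mesh import TissueMesh


def write_vtk(mesh: TissueMesh, path, point_data: dict | None = None) -> None:
    """Write the mesh and its labels (plus extra point fields) to legacy VTK."""
    fields = {
        "cell_type": mesh.cell_type.astype(np.int32),
        "region": mesh.region.astype(np.int32),
        "longitudinal": mesh.longitudinal.astype(np.int32),
        "ndepth": mesh.ndepth.astype(float),
    }
    if point_data:
        fields.update({k: np.asarray(v) for k, v in point_data.items()})
    n = mesh.n_nodes
    tets = mesh.elements
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"cardioem mesh seed={mesh.seed} spacing={mesh.spacing}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.8g")
        fh.write(f"CELLS {len(tets)} {len(tets) * 5}\n")
        if len(tets):
            np.savetxt(fh, np.column_stack([np.full(len(tets), 4), tets]), fmt="%d")
        fh.write(f"CELL_TYPES {len(tets)}\n")
        if len(tets):
            np.savetxt(fh, np.full(len(tets), 10), fmt="%d")
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in fields.items():
            if np.issubdtype(arr.dtype, np.integer):
                fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%d")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, arr, fmt="%.8g")


def read_vtk(path) -> tuple[TissueMesh, dict]:
    """Read a legacy-VTK tetrahedral mesh written by :func:`write_vtk`.

    Returns the mesh and a dict of any extra point-data fields.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    it = iter(range(len(tokens)))

    def find(prefix, start=0):
        for k in range(start, len(tokens)):
            if tokens[k].startswith(prefix):
                return k
        raise ValueError(f"missing section {prefix!r} in {path}")

    k = find("POINTS")
    n = int(tokens[k].split()[1])
    vals = " ".join(tokens[k + 1:]).split()
    # points occupy the next 3n floats
    pts = np.array(vals[: 3 * n], dtype=float).reshape(n, 3)

    k = find("CELLS", k)
    m = int(tokens[k].split()[1])
    cell_vals = []
    row = k + 1
    while len(cell_vals) < 5 * m:
        cell_vals.extend(tokens[row].split())
        row += 1
    cells = np.array(cell_vals, dtype=np.int64).reshape(m, 5)[:, 1:] if m else \
        np.empty((0, 4), dtype=np.int64)

    k = find("POINT_DATA", k)
    fields = {}
    row = k + 1
    while row < len(tokens):
        line = tokens[row].strip()
        if not line.startswith("SCALARS"):
            row += 1
            continue
        _, name, dtype = line.split()[:3]
        row += 2  # skip LOOKUP_TABLE
        vals = []
        while len(vals) < n:
            vals.extend(tokens[row].split())
            row += 1
        fields[name] = np.array(vals, dtype=int if dtype == "int" else float)

    spacing = 0.0
    for tok in tokens[1].split():
        if tok.startswith("spacing="):
            spacing = float(tok.split("=")[1])
    mesh = TissueMesh(
        nodes=pts, elements=cells, spacing=spacing or 0.1,
        edges=_edges_from_tets(cells, n),
        cell_type=fields.pop("cell_type", np.zeros(n)).astype(np.int8),
        region=fields.pop("region", np.zeros(n)).astype(np.int8),
        longitudinal=fields.pop("longitudinal", np.zeros(n)).astype(np.int8),
        ndepth=fields.pop("ndepth", np.zeros(n)).astype(float),
        meta={"source": str(path)},
    )
    return mesh, fields


def _edges_from_tets(tets: np.ndarray, n_nodes: int) -> np.ndarray:
    """Unique undirected edges of a tet mesh (axis tag 0; external meshes
    are treated as isotropic)."""
    if not len(tets):
        return np.empty((0, 3), dtype=np.int64)
    pairs = np.concatenate([tets[:, [a, b]]
                            for a, b in ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))])
    pairs = np.sort(pairs, axis=1)
    pairs = np.unique(pairs, axis=0)
    return np.column_stack([pairs, np.zeros(len(pairs), dtype=np.int64)])


def write_table(frame, path, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV with '#' metadata header lines."""
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        frame.to_csv(fh, index=False)
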