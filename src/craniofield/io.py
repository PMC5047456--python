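"""Serialization: Gmsh MSH v2.2 ASCII, VTU (XML ASCII) and YAML configs.

MSH carries the mesh with element physical tags = tissue codes; VTU carries
the mesh plus arbitrary per-cell / per-point data arrays (labels, region
flags, fields, symmetric tensors as 6 components in xx yy zz xy yz xz
order).  Both formats are plain text so artifacts stay diff-able.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import yaml

from .mesh import VolumeMesh

__all__ = ["write_msh", "read_msh", "write_vtu", "load_config", "dump_config"]


def write_msh(path, mesh: VolumeMesh) -> None:
    """Write the mesh as Gmsh MSH v2.2 ASCII with physical tag = label."""
    buf = _io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    buf.write(f"$Nodes\n{mesh.n_nodes}\n")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        buf.write(f"{i} {x:.10g} {y:.10g} {z:.10g}\n")
    buf.write("$EndNodes\n")
    buf.write(f"$Elements\n{mesh.n_elements}\n")
    # element type 4 = 4-node tetrahedron; tags: physical, geometric
    for i, (tet, lab) in enumerate(zip(mesh.tets, mesh.labels), start=1):
        a, b, c, d = tet + 1
        buf.write(f"{i} 4 2 {lab} {lab} {a} {b} {c} {d}\n")
    buf.write("$EndElements\n")
    Path(path).write_text(buf.getvalue())


def read_msh(path) -> VolumeMesh:
    """Read an MSH v2.2 ASCII file written by :func:`write_msh` (tets only)."""
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    nodes, node_ids, tets, labels = [], [], [], []
    for line in it:
        if line.startswith("$Nodes"):
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                node_ids.append(int(parts[0]))
                nodes.append([float(v) for v in parts[1:4]])
        elif line.startswith("$Elements"):
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                etype, ntags = int(parts[1]), int(parts[2])
                if etype != 4:
                    continue
                labels.append(int(parts[3]) if ntags >= 1 else 0)
                tets.append([int(v) for v in parts[3 + ntags:7 + ntags]])
    remap = {nid: i for i, nid in enumerate(node_ids)}
    tets = np.array([[remap[v] for v in t] for t in tets], dtype=np.int64)
    return VolumeMesh(np.array(nodes), tets, np.array(labels, dtype=np.int64))


def _fmt_array(a: np.ndarray) -> str:
    a = np.asarray(a)
    if a.dtype.kind in "iub":
        return "\n".join(" ".join(str(int(v)) for v in row)
                         for row in np.atleast_2d(a.reshape(len(a), -1)))
    return "\n".join(" ".join(f"{v:.9g}" for v in row)
                     for row in np.atleast_2d(a.reshape(len(a), -1)))


def _sym6(tensors: np.ndarray) -> np.ndarray:
    """(M, 3, 3) symmetric tensors -> (M, 6) xx yy zz xy yz xz."""
    t = np.asarray(tensors)
    return np.stack([t[:, 0, 0], t[:, 1, 1], t[:, 2, 2],
                     t[:, 0, 1], t[:, 1, 2], t[:, 0, 2]], axis=1)


def write_vtu(path, mesh: VolumeMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write an unstructured-grid VTU (XML, ASCII) with optional data arrays.

    3-D tensor-valued cell arrays of shape (M, 3, 3) are flattened to 6
    symmetric components.  Region flags in ``mesh.flags`` are always
    exported as per-cell integer arrays, alongside the label array.
    """
    cell_data = dict(cell_data or {})
    cell_data.setdefault("tissue", mesh.labels)
    for name, flag in mesh.flags.items():
        cell_data.setdefault(f"flag_{name}", flag.astype(np.int32))

    n_pts, n_cells = mesh.n_nodes, mesh.n_elements
    parts = ['<?xml version="1.0"?>',
             '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
             '<UnstructuredGrid>',
             f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">']

    def data_array(name, a):
        a = np.asarray(a)
        if a.ndim == 3 and a.shape[1:] == (3, 3):
            a = _sym6(a)
        ncomp = 1 if a.ndim == 1 else a.shape[1]
        typ = "Int32" if a.dtype.kind in "iub" else "Float64"
        return (f'<DataArray type="{typ}" Name="{name}" '
                f'NumberOfComponents="{ncomp}" format="ascii">\n'
                + _fmt_array(a) + "\n</DataArray>")

    parts.append("<Points>")
    parts.append(data_array("Points", mesh.nodes.reshape(-1, 3)))
    parts.append("</Points>")
    parts.append("<Cells>")
    parts.append(data_array("connectivity", mesh.tets.reshape(-1, 1)))
    parts.append(data_array("offsets", 4 * np.arange(1, n_cells + 1)))
    parts.append(data_array("types", np.full(n_cells, 10, dtype=np.int32)))
    parts.append("</Cells>")
    if point_data:
        parts.append("<PointData>")
        for k, v in point_data.items():
            parts.append(data_array(k, v))
        parts.append("</PointData>")
    parts.append("<CellData>")
    for k, v in cell_data.items():
        parts.append(data_array(k, v))
    parts.append("</CellData>")
    parts += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(parts))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def dump_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
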