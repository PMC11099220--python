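"""Mesh and surface I/O in plain-text dialects.

Volume meshes round-trip through two formats:

* tetgen ``.node`` / ``.ele`` pairs (1-based indices, the region label
  stored as the element attribute), and
* ASCII VTU (VTK unstructured grid, tetra cells, cell-data array
  ``region``).

Surfaces export to OFF and ASCII STL.  Potentials export as CSV
(x, y, z, potential).  All meshes are labeled; reading a volume mesh
without region information is an error asking the user to supply labels.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import InterfaceSurface, LabeledTetMesh
from .solution import ForwardSolution


def write_mesh(mesh: LabeledTetMesh, path: str | Path) -> None:
    """Write a labeled tet mesh; format chosen by extension (.node -> tetgen
    pair, .vtu -> ASCII VTU)."""
    path = Path(path)
    if path.suffix == ".node":
        _write_tetgen(mesh, path)
    elif path.suffix == ".vtu":
        _write_vtu(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r} "
                         "(use .node or .vtu)")


def read_mesh(path: str | Path) -> LabeledTetMesh:
    path = Path(path)
    if path.suffix in (".node", ".ele"):
        return _read_tetgen(path.with_suffix(".node"))
    if path.suffix == ".vtu":
        return _read_vtu(path)
    raise ValueError(f"unsupported mesh format {path.suffix!r}")


# ---------------------------------------------------------------- tetgen ---

def _write_tetgen(mesh: LabeledTetMesh, node_path: Path) -> None:
    with open(node_path, "w") as f:
        f.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {float(x)!r} {float(y)!r} {float(z)!r}\n")
    with open(node_path.with_suffix(".ele"), "w") as f:
        f.write(f"{mesh.n_tets} 4 1\n")
        for i, (tet, lab) in enumerate(zip(mesh.tets, mesh.region_label),
                                       start=1):
            a, b, c, d = tet + 1
            f.write(f"{i} {a} {b} {c} {d} {lab}\n")


def _read_tetgen(node_path: Path) -> LabeledTetMesh:
    with open(node_path) as f:
        header = f.readline().split()
        n = int(header[0])
        nodes = np.empty((n, 3))
        idx = np.empty(n, np.int64)
        for k in range(n):
            parts = f.readline().split()
            idx[k] = int(parts[0])
            nodes[k] = [float(p) for p in parts[1:4]]
    base = int(idx.min())            # tetgen files may be 0- or 1-based
    ele_path = node_path.with_suffix(".ele")
    with open(ele_path) as f:
        header = f.readline().split()
        m, _nper, nattr = int(header[0]), int(header[1]), int(header[2])
        if nattr < 1:
            raise ValueError(
                f"{ele_path} has no region attribute; supply per-element "
                "region labels (tetgen -A or a VTU with cell data 'region')")
        tets = np.empty((m, 4), np.int64)
        labels = np.empty(m, np.int64)
        for k in range(m):
            parts = f.readline().split()
            tets[k] = [int(p) - base for p in parts[1:5]]
            labels[k] = int(float(parts[5]))
    mesh = LabeledTetMesh(nodes=nodes, tets=tets, region_label=labels,
                          provenance={"source": str(node_path)})
    mesh.orient_positive()
    return mesh


# ------------------------------------------------------------------- VTU ---

def _write_vtu(mesh: LabeledTetMesh, path: Path) -> None:
    n, m = mesh.n_nodes, mesh.n_tets
    pts = " ".join(repr(float(v)) for v in mesh.nodes.ravel())
    conn = " ".join(str(v) for v in mesh.tets.ravel())
    offs = " ".join(str(4 * (i + 1)) for i in range(m))
    types = " ".join("10" for _ in range(m))
    regs = " ".join(str(v) for v in mesh.region_label)
    path.write_text(f"""<?xml version="1.0"?>
<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">
 <UnstructuredGrid>
  <Piece NumberOfPoints="{n}" NumberOfCells="{m}">
   <Points>
    <DataArray type="Float64" NumberOfComponents="3" format="ascii">{pts}</DataArray>
   </Points>
   <Cells>
    <DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>
    <DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>
    <DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>
   </Cells>
   <CellData Scalars="region">
    <DataArray type="Int64" Name="region" format="ascii">{regs}</DataArray>
   </CellData>
  </Piece>
 </UnstructuredGrid>
</VTKFile>
""")


def _read_vtu(path: Path) -> LabeledTetMesh:
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = _array(piece.find("Points/DataArray"), float).reshape(-1, 3)
    arrays = {da.get("Name"): da for da in piece.find("Cells")}
    conn = _array(arrays["connectivity"], np.int64)
    offs = _array(arrays["offsets"], np.int64)
    types = _array(arrays["types"], np.int64)
    if not np.all(types == 10):
        raise ValueError("VTU contains non-tetrahedral cells")
    tets = conn.reshape(-1, 4)
    if not np.array_equal(offs, 4 * np.arange(1, len(tets) + 1)):
        raise ValueError("unexpected VTU offsets for tetra cells")
    cell_data = piece.find("CellData")
    region = None
    if cell_data is not None:
        for da in cell_data:
            if da.get("Name") == "region":
                region = _array(da, np.int64)
    if region is None:
        raise ValueError(
            f"{path} has no cell-data array 'region'; supply per-element "
            "region labels")
    mesh = LabeledTetMesh(nodes=pts, tets=tets, region_label=region,
                          provenance={"source": str(path)})
    mesh.orient_positive()
    return mesh


def _array(da, dtype):
    return np.array(da.text.split(), dtype=dtype)


# -------------------------------------------------------------- surfaces ---

def write_surface(surface: InterfaceSurface, path: str | Path) -> None:
    """Write a triangulated surface as OFF or ASCII STL."""
    path = Path(path)
    used = np.unique(surface.triangles)
    remap = -np.ones(surface.nodes.shape[0], np.int64)
    remap[used] = np.arange(used.size)
    verts = surface.nodes[used]
    tris = remap[surface.triangles]
    if path.suffix == ".off":
        lines = ["OFF", f"{len(verts)} {len(tris)} 0"]
        lines += [f"{float(x)!r} {float(y)!r} {float(z)!r}" for x, y, z in verts]
        lines += [f"3 {a} {b} {c}" for a, b, c in tris]
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix == ".stl":
        normals = surface.normals()
        out = ["solid surface"]
        for (a, b, c), n in zip(tris, normals):
            out.append(f" facet normal {float(n[0])!r} {float(n[1])!r} {float(n[2])!r}")
            out.append("  outer loop")
            for v in (a, b, c):
                x, y, z = verts[v]
                out.append(f"   vertex {float(x)!r} {float(y)!r} {float(z)!r}")
            out.append("  endloop")
            out.append(" endfacet")
        out.append("endsolid surface")
        path.write_text("\n".join(out) + "\n")
    else:
        raise ValueError(f"unsupported surface format {path.suffix!r}")


def write_potentials_csv(sol: ForwardSolution, path: str | Path) -> None:
    """Export a forward solution as x,y,z,potential CSV."""
    arr = np.column_stack([sol.points, sol.potentials])
    header = "x_m,y_m,z_m,potential_V"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
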