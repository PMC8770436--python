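"""Minimal ASCII VTK unstructured-grid (.vtu) writer and reader.

Writes hexahedral meshes with point and cell data in the XML VTU format
readable by ParaView/VTK; the reader exists to round-trip files in tests.
Coordinates are written with full double precision (repr round-trip safe).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .geometry import HexMesh

__all__ = ["write_vtu", "read_vtu"]

_VTK_HEX = 12
_VTK_TET = 10


def _fmt(arr: np.ndarray) -> str:
    a = np.asarray(arr)
    if np.issubdtype(a.dtype, np.integer):
        return " ".join(str(int(v)) for v in a.ravel())
    return " ".join(repr(float(v)) for v in a.ravel())


def _data_array(parent, name, arr, n_comp=None):
    a = np.asarray(arr)
    dtype = "Int64" if np.issubdtype(a.dtype, np.integer) else "Float64"
    attrs = {"type": dtype, "Name": name, "format": "ascii"}
    if n_comp:
        attrs["NumberOfComponents"] = str(n_comp)
    el = ET.SubElement(parent, "DataArray", attrs)
    el.text = _fmt(a)
    return el


def write_vtu(mesh: HexMesh, path: str | Path,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh with optional nodal and per-element fields.

    Field arrays must have leading dimension equal to the node count
    (``point_data``) or element count (``cell_data``); vector fields may
    have a trailing component dimension.
    """
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.region.astype(np.int64))
    for name, a in point_data.items():
        if np.asarray(a).shape[0] != mesh.n_nodes:
            raise ValueError(f"point data {name!r} length != node count")
    for name, a in cell_data.items():
        if np.asarray(a).shape[0] != mesh.n_elements:
            raise ValueError(f"cell data {name!r} length != element count")

    root = ET.Element("VTKFile", {"type": "UnstructuredGrid",
                                  "version": "0.1", "byte_order": "LittleEndian"})
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece",
                          {"NumberOfPoints": str(mesh.n_nodes),
                           "NumberOfCells": str(mesh.n_elements)})
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, "Points", mesh.nodes, n_comp=3)

    cells = ET.SubElement(piece, "Cells")
    _data_array(cells, "connectivity", mesh.elements.astype(np.int64))
    _data_array(cells, "offsets",
                8 * np.arange(1, mesh.n_elements + 1, dtype=np.int64))
    _data_array(cells, "types",
                np.full(mesh.n_elements, _VTK_HEX, dtype=np.int64))

    if point_data:
        pd_el = ET.SubElement(piece, "PointData")
        for name, a in point_data.items():
            a = np.asarray(a)
            nc = a.shape[1] if a.ndim > 1 else None
            _data_array(pd_el, name, a, n_comp=nc)
    cd_el = ET.SubElement(piece, "CellData")
    for name, a in cell_data.items():
        a = np.asarray(a)
        nc = a.shape[1] if a.ndim > 1 else None
        _data_array(cd_el, name, a, n_comp=nc)

    ET.ElementTree(root).write(Path(path), xml_declaration=True,
                               encoding="utf-8")


def read_vtu(path: str | Path):
    """Read a file written by :func:`write_vtu`.

    Returns ``(nodes, connectivity, point_data, cell_data)``.
    """
    piece = ET.parse(Path(path)).getroot().find("./UnstructuredGrid/Piece")
    if piece is None:
        raise ValueError("not a VTU unstructured-grid file")

    def parse(el):
        is_int = el.get("type").startswith("Int")
        a = np.array(el.text.split(),
                     dtype=np.int64 if is_int else np.float64)
        nc = el.get("NumberOfComponents")
        return a.reshape(-1, int(nc)) if nc else a

    nodes = parse(piece.find("./Points/DataArray"))
    arrays = {el.get("Name"): parse(el)
              for el in piece.findall("./Cells/DataArray")}
    conn = arrays["connectivity"].reshape(-1, 8)
    point_data = {el.get("Name"): parse(el)
                  for el in piece.findall("./PointData/DataArray")}
    cell_data = {el.get("Name"): parse(el)
                 for el in piece.findall("./CellData/DataArray")}
    return nodes, conn, point_data, cell_data
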