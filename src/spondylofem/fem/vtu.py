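"""Minimal ASCII VTU (VTK XML unstructured grid) writer.

Writes hexahedral cells with optional point and cell data arrays — enough
to inspect meshes and stress fields in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_VTK_HEXAHEDRON = 12


def _data_array(name: str, data: np.ndarray, ncomp: int) -> str:
    flat = np.asarray(data, dtype=float).reshape(-1)
    body = " ".join(f"{v:.9g}" for v in flat)
    return (f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">{body}</DataArray>')


def write_vtu(path: str | Path, points: np.ndarray, hex_conn: np.ndarray,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write points + hexahedral cells (+ data arrays) as an ASCII .vtu."""
    points = np.asarray(points, dtype=float)
    conn = np.asarray(hex_conn, dtype=int).reshape(-1, 8)
    ncell = conn.shape[0]
    offsets = " ".join(str(8 * (i + 1)) for i in range(ncell))
    types = " ".join(str(_VTK_HEXAHEDRON) for _ in range(ncell))
    connectivity = " ".join(str(int(v)) for v in conn.ravel())

    pd = ""
    if point_data:
        arrays = []
        for name, arr in point_data.items():
            a = np.asarray(arr)
            ncomp = 1 if a.ndim == 1 else int(np.prod(a.shape[1:]))
            arrays.append(_data_array(name, a, ncomp))
        pd = "<PointData>" + "".join(arrays) + "</PointData>"
    cd = ""
    if cell_data:
        arrays = []
        for name, arr in cell_data.items():
            a = np.asarray(arr)
            ncomp = 1 if a.ndim == 1 else int(np.prod(a.shape[1:]))
            arrays.append(_data_array(name, a, ncomp))
        cd = "<CellData>" + "".join(arrays) + "</CellData>"

    xml = (
        '<?xml version="1.0"?>\n'
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">\n'
        '<UnstructuredGrid>\n'
        f'<Piece NumberOfPoints="{points.shape[0]}" NumberOfCells="{ncell}">\n'
        f'<Points>{_data_array("points", points, 3)}</Points>\n'
        '<Cells>'
        f'<DataArray type="Int64" Name="connectivity" format="ascii">'
        f'{connectivity}</DataArray>'
        f'<DataArray type="Int64" Name="offsets" format="ascii">'
        f'{offsets}</DataArray>'
        f'<DataArray type="UInt8" Name="types" format="ascii">'
        f'{types}</DataArray>'
        '</Cells>\n'
        f'{pd}{cd}\n'
        '</Piece>\n</UnstructuredGrid>\n</VTKFile>\n'
    )
    Path(path).write_text(xml)
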