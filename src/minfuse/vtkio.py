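"""Legacy ASCII VTK unstructured-grid export of voxel meshes.

Writes points, hexahedral cells and per-cell / per-point scalar arrays so
the mesh, material map and stress fields can be inspected in ParaView.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from .fem import VoxelMesh

_VTK_HEXAHEDRON = 12


def write_vtk(
    mesh: VoxelMesh,
    path: str | os.PathLike,
    cell_data: Mapping[str, np.ndarray] | None = None,
    point_data: Mapping[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh with optional scalar/vector data arrays."""
    cell_data = cell_data or {}
    point_data = point_data or {}
    nelem, nnode = mesh.n_elements, mesh.n_nodes
    for name, arr in cell_data.items():
        if len(arr) != nelem:
            raise ValueError(f"cell data {name!r} has wrong length")
    for name, arr in point_data.items():
        if len(arr) != nnode:
            raise ValueError(f"point data {name!r} has wrong length")

    with open(os.fspath(path), "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("minfuse voxel mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {nnode} double\n")
        np.savetxt(fh, mesh.nodes_xyz, fmt="%.9g")
        fh.write(f"CELLS {nelem} {nelem * 9}\n")
        cells = np.column_stack(
            [np.full(nelem, 8, dtype=np.int64), mesh.connectivity])
        np.savetxt(fh, cells, fmt="%d")
        fh.write(f"CELL_TYPES {nelem}\n")
        np.savetxt(fh, np.full(nelem, _VTK_HEXAHEDRON, dtype=np.int64), fmt="%d")
        if cell_data:
            fh.write(f"CELL_DATA {nelem}\n")
            for name, arr in cell_data.items():
                _write_array(fh, name, np.asarray(arr))
        if point_data:
            fh.write(f"POINT_DATA {nnode}\n")
            for name, arr in point_data.items():
                _write_array(fh, name, np.asarray(arr))


def _write_array(fh, name: str, arr: np.ndarray) -> None:
    if arr.ndim == 2 and arr.shape[1] == 3:
        fh.write(f"VECTORS {name} double\n")
        np.savetxt(fh, arr, fmt="%.9g")
        return
    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
    np.savetxt(fh, arr.reshape(-1, 1), fmt="%.9g")
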