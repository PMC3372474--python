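"""Legacy ASCII VTK export of the structured mesh and cell fields.

Writes RECTILINEAR_GRID files readable by ParaView/VisIt.  Write-only and
deliberately minimal: the mesh is rectilinear, so the legacy format needs
only the three coordinate arrays plus CELL_DATA blocks.
"""

from __future__ import annotations

import numpy as np

from .geometry import Mesh


def write_vtk(path, mesh: Mesh, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and optional per-cell scalar fields to legacy VTK.

    ``cell_data`` maps field names to arrays of shape ``mesh.shape``; the
    zone labels are always included.
    """
    nx, ny, nz = mesh.shape
    fields = {"zone": mesh.zone.astype(float)}
    if cell_data:
        for name, arr in cell_data.items():
            if arr.shape != mesh.shape:
                raise ValueError(f"field {name!r} has shape {arr.shape}, expected {mesh.shape}")
            fields[name] = np.asarray(arr, dtype=float)

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncoraltherm rectilinear mesh\nASCII\n")
        f.write("DATASET RECTILINEAR_GRID\n")
        f.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        for name, arr in (("X", mesh.xf), ("Y", mesh.yf), ("Z", mesh.zf)):
            f.write(f"{name}_COORDINATES {len(arr)} double\n")
            f.write(" ".join(f"{v:.9g}" for v in arr) + "\n")
        f.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK cell ordering: x fastest, then y, then z
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            f.write("\n".join(f"{v:.9g}" for v in flat) + "\n")
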