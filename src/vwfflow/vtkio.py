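"""Minimal legacy-VTK ASCII export of structured (r, z) fields.

Write-only: enough for inspection in ParaView/VisIt.  The body-fitted
grid is emitted as a ``STRUCTURED_GRID`` with points (z, r, 0) and
per-point scalar fields.
"""

from __future__ import annotations

import numpy as np

from .geometry import StretchedGrid

__all__ = ["write_vtk"]


def write_vtk(path, grid: StretchedGrid, point_data: dict[str, np.ndarray], title="vwfflow"):
    """Write scalar point fields on the grid to a legacy ASCII .vtk file."""
    ny, nz = grid.shape
    r = grid.r
    z = grid.zz
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{title}\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {nz} {ny} 1\n")
        fh.write(f"POINTS {ny * nz} double\n")
        pts = np.column_stack([z.ravel(), r.ravel(), np.zeros(ny * nz)])
        np.savetxt(fh, pts, fmt="%.9g")
        fh.write(f"\nPOINT_DATA {ny * nz}\n")
        for name, data in point_data.items():
            data = np.asarray(data, dtype=float)
            if data.shape != (ny, nz):
                raise ValueError(f"field {name} has shape {data.shape}, expected {(ny, nz)}")
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, data.ravel()[:, None], fmt="%.9g")
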