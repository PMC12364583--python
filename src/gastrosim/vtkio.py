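"""Minimal legacy-VTK ASCII writers for field snapshots and outlines.

Structured-points files carry cell-centred velocity/pressure/solid-fraction
fields; polydata files carry the lumen boundary and particle outlines.  The
legacy ASCII format is simple enough that a dedicated dependency is not
warranted.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_structured_points", "write_polylines"]


def write_structured_points(path, origin, h, fields: dict[str, np.ndarray]) -> None:
    """Write cell-centred scalar/vector fields as VTK structured points.

    ``fields`` maps names to (nx, ny) arrays (scalars) or (nx, ny, 2) arrays
    (vectors, written with a zero z-component).
    """
    first = next(iter(fields.values()))
    nx, ny = first.shape[:2]
    lines = [
        "# vtk DataFile Version 3.0",
        "gastrosim snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {origin[0] + h / 2} {origin[1] + h / 2} 0",
        f"SPACING {h} {h} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, arr in fields.items():
        if arr.ndim == 2:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            # VTK iterates x fastest
            lines.extend(" ".join(f"{v:.6g}" for v in arr[:, j]) for j in range(ny))
        else:
            lines.append(f"VECTORS {name} double")
            for j in range(ny):
                lines.append(
                    " ".join(f"{arr[i, j, 0]:.6g} {arr[i, j, 1]:.6g} 0" for i in range(nx))
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_polylines(path, polylines: list[np.ndarray]) -> None:
    """Write 2D polylines (lumen boundary, particle outlines) as VTK polydata."""
    npts = sum(len(p) for p in polylines)
    lines = [
        "# vtk DataFile Version 3.0",
        "gastrosim outlines",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {npts} double",
    ]
    for poly in polylines:
        lines.extend(f"{x:.6g} {y:.6g} 0" for x, y in poly)
    size = sum(len(p) + 1 for p in polylines)
    lines.append(f"LINES {len(polylines)} {size}")
    off = 0
    for poly in polylines:
        lines.append(str(len(poly)) + " " + " ".join(str(off + k) for k in range(len(poly))))
        off += len(poly)
    Path(path).write_text("\n".join(lines) + "\n")
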