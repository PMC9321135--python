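"""Minimal legacy-VTK (structured points, ASCII) writer for field dumps.

The structured-points flavour is sufficient for the Cartesian grids used
here and keeps the output plain text; files open directly in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vtk_structured_points(
    path,
    fields: dict[str, np.ndarray],
    spacing: float,
    origin=(0.0, 0.0, 0.0),
) -> Path:
    """Write scalar/vector cell fields on a regular grid.

    ``fields`` maps name -> array; scalars have the grid shape, vectors
    have shape (d, *grid).  2D grids are written as one-cell-thick 3D.
    """
    path = Path(path)
    if not fields:
        raise ValueError("no fields to write")
    # infer the grid shape from any scalar field, else from a vector field
    grid = None
    for arr in fields.values():
        if arr.ndim in (2, 3) and not _is_vector(arr):
            grid = arr.shape
            break
    if grid is None:
        arr = next(iter(fields.values()))
        grid = arr.shape[1:]
    dims = tuple(grid) + (1,) * (3 - len(grid))

    lines = [
        "# vtk DataFile Version 3.0",
        "mfsim field dump",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
        f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
        f"SPACING {spacing} {spacing} {spacing}",
        f"POINT_DATA {dims[0] * dims[1] * dims[2]}",
    ]
    for name, arr in fields.items():
        if _is_vector(arr):
            d = arr.shape[0]
            comps = [arr[a] for a in range(d)] + [np.zeros(grid)] * (3 - d)
            flat = np.stack(
                [c.reshape(grid).flatten(order="F") for c in comps], axis=1
            )
            lines.append(f"VECTORS {name} double")
            lines.extend(" ".join(f"{v:.9g}" for v in row) for row in flat)
        else:
            if arr.shape != tuple(grid):
                raise ValueError(f"field {name!r} shape {arr.shape} != grid {grid}")
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            flat = arr.flatten(order="F")
            lines.extend(f"{v:.9g}" for v in flat)
    path.write_text("\n".join(lines) + "\n")
    return path


def _is_vector(arr: np.ndarray) -> bool:
    # convention: vectors are (d, *grid) with d == grid dimensionality
    return (arr.ndim == 3 and arr.shape[0] == 2) or (arr.ndim == 4 and arr.shape[0] == 3)


def read_vtk_header(path) -> dict:
    """Parse the header of a structured-points file (for validation)."""
    info = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "DIMENSIONS":
                info["dimensions"] = tuple(int(p) for p in parts[1:4])
            elif parts[0] == "SPACING":
                info["spacing"] = tuple(float(p) for p in parts[1:4])
            elif parts[0] == "POINT_DATA":
                info["n_points"] = int(parts[1])
            elif parts[0] in ("SCALARS", "VECTORS"):
                info.setdefault("fields", []).append((parts[0].lower(), parts[1]))
    return info
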