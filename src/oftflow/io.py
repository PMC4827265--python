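"""File output helpers: legacy-VTK volume meshes, PLY surfaces, CSV tables.

Surface meshes go through trimesh (PLY/STL); tetrahedral volume meshes and
point fields are written as legacy ASCII VTK unstructured grids, which every
mainstream viewer (ParaView, VisIt) reads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_vtk_unstructured", "save_surface_series"]

_VTK_TETRA = 10


def write_vtk_unstructured(path, nodes: np.ndarray, tets: np.ndarray, point_data=None):
    """Write a tetrahedral mesh with optional per-node fields (legacy VTK)."""
    nodes = np.asarray(nodes, dtype=float)
    tets = np.asarray(tets, dtype=np.int64)
    point_data = point_data or {}
    lines = [
        "# vtk DataFile Version 3.0",
        "oftflow unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(nodes)} double",
    ]
    lines += [" ".join(f"{v:.10e}" for v in p) for p in nodes]
    lines.append(f"CELLS {len(tets)} {len(tets) * 5}")
    lines += ["4 " + " ".join(str(i) for i in t) for t in tets]
    lines.append(f"CELL_TYPES {len(tets)}")
    lines += [str(_VTK_TETRA)] * len(tets)
    if point_data:
        lines.append(f"POINT_DATA {len(nodes)}")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines += [f"{v:.10e}" for v in arr]
            else:
                lines.append(f"VECTORS {name} double")
                lines += [" ".join(f"{v:.10e}" for v in row) for row in arr]
    Path(path).write_text("\n".join(lines) + "\n")


def save_surface_series(frames, outdir, prefix: str):
    """Export a surface sequence as numbered PLY files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for j, frame in enumerate(frames):
        frame.save_ply(outdir / f"{prefix}_{j:03d}.ply")
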