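"""Writers (VTK image data, CSV series, STL) and checkpointing.

Snapshots go out as ASCII VTK XML ImageData (.vti) readable by ParaView and
friends; metric time series as CSV through pandas (missing metrics stay
empty cells, never 0); isosurfaces as STL through trimesh.  Checkpoints are
npz archives carrying the complete solver state so a reloaded run continues
bit-identically.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_vti", "write_series", "write_stl", "save_checkpoint",
           "load_checkpoint", "write_summary"]


def write_vti(path, grid, cell_data: dict):
    """Minimal ASCII VTK XML ImageData writer for cell-centered fields.

    ``cell_data`` maps names to arrays shaped grid.shape3 (scalars) or
    (ncomp,) + grid.shape3 (vectors/tensors, written componentwise).
    """
    nx, ny, nz = grid.shape3
    dx = grid.dx
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="ImageData" version="0.1" byte_order="LittleEndian">',
        f'  <ImageData WholeExtent="0 {nx} 0 {ny} 0 {nz}" '
        f'Origin="0 0 0" Spacing="{dx} {dx} {dx}">',
        f'    <Piece Extent="0 {nx} 0 {ny} 0 {nz}">',
        '      <CellData>',
    ]
    for name, arr in cell_data.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            comps = [(name, arr)]
        else:
            comps = [(f"{name}_{i}", arr[i]) for i in range(arr.shape[0])]
        for cname, c in comps:
            flat = np.asarray(c, float).transpose(2, 1, 0).ravel()
            body = " ".join(f"{v:.9g}" for v in flat)
            lines.append(
                f'        <DataArray type="Float64" Name="{cname}" '
                'format="ascii">')
            lines.append("          " + body)
            lines.append('        </DataArray>')
    lines += ['      </CellData>', '    </Piece>', '  </ImageData>',
              '</VTKFile>']
    Path(path).write_text("\n".join(lines) + "\n")
    return path


def write_series(rows, columns, path):
    """CSV metric series; ``rows`` is an iterable of tuples aligned with
    ``columns``; None entries become empty cells."""
    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, index=False)
    return path


def write_stl(path, verts, faces):
    import trimesh
    mesh = trimesh.Trimesh(vertices=np.asarray(verts),
                           faces=np.asarray(faces), process=False)
    mesh.export(path)
    return path


def save_checkpoint(path, state: dict):
    """Persist the full solver state (arrays + scalars + config hash)."""
    arrays = {}
    scalars = {}
    for k, v in state.items():
        if isinstance(v, np.ndarray):
            arrays[k] = v
        else:
            scalars[k] = v
    arrays["__meta__"] = np.frombuffer(
        json.dumps(scalars, default=float).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> dict:
    with np.load(path) as z:
        out = {k: z[k].copy() for k in z.files if k != "__meta__"}
        meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
    out.update(meta)
    return out


def write_summary(path, summary: dict):
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return path
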