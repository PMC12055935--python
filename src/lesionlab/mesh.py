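"""Tessellation and mesh export for lesion solids.

Per-label surface meshes (STL) are produced by voxelizing the semi-analytic
solid and running marching cubes, which yields closed, watertight shells and
preserves the topology of carved calcium (a through defect exports as two
shells).  Volume export writes a VTK legacy unstructured grid of hexahedral
cells carrying an integer ``material_id`` cell array.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import trimesh
from skimage import measure

from .geometry import MATERIAL_IDS, LesionSolid

__all__ = ["voxelize", "tessellate_label", "tessellate_and_export", "write_vtk_unstructured"]

log = logging.getLogger(__name__)


def _grid(solid: LesionSolid, pitch: float, z_window: tuple[float, float] | None):
    c = solid.config
    rmax = c.calcium_outer_radius + c.media_thickness + c.adventitia_thickness
    z0, z1 = z_window if z_window is not None else (0.0, c.artery_length)
    xs = np.arange(-rmax - pitch, rmax + 2 * pitch, pitch)
    ys = xs.copy()
    zs = np.arange(z0 - pitch, z1 + 2 * pitch, pitch)
    return xs, ys, zs


def voxelize(
    solid: LesionSolid,
    pitch: float = 0.15,
    z_window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Material-id voxel grid sampled at cell centers.

    Returns ``(ids, (xs, ys, zs))`` where ids has shape (nx, ny, nz).
    """
    xs, ys, zs = _grid(solid, pitch, z_window)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    return solid.material_at(X, Y, Z), (xs, ys, zs)


def tessellate_label(
    solid: LesionSolid,
    label: str,
    pitch: float = 0.15,
    z_window: tuple[float, float] | None = None,
) -> trimesh.Trimesh | None:
    """Watertight surface mesh of one material label, or None if absent."""
    if label not in MATERIAL_IDS:
        raise ValueError(f"unknown material label {label!r}")
    if label == "calcium" and z_window is None:
        # calcium only exists in the lesion window; restrict for resolution
        z0, z1 = solid.config.lesion_z_window
        z_window = (z0 - 1.0, z1 + 1.0)
    ids, (xs, ys, zs) = voxelize(solid, pitch, z_window)
    occ = (ids == MATERIAL_IDS[label]).astype(np.float32)
    if occ.sum() == 0:
        log.warning("label %r is empty; no mesh produced", label)
        return None
    occ = np.pad(occ, 1)  # closed isosurface even at the grid boundary
    verts, faces, _, _ = measure.marching_cubes(occ, level=0.5)
    origin = np.array([xs[0] - pitch, ys[0] - pitch, zs[0] - pitch])
    verts = verts * pitch + origin
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    return mesh


def tessellate_and_export(
    solid: LesionSolid,
    fmt: str,
    path: str | Path,
    pitch: float = 0.15,
    labels: Iterable[str] | None = None,
) -> list[Path]:
    """Export the solid's material labels as mesh files.

    ``fmt='stl'`` writes one binary STL per non-empty label under ``path``
    (a directory); ``fmt='vtk'`` writes a single legacy unstructured grid
    with integer cell data ``material_id`` to ``path`` (a file).  Returns the
    written paths.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "stl":
        path.mkdir(parents=True, exist_ok=True)
        labels = list(labels) if labels else [k for k in MATERIAL_IDS if k != "lumen"]
        written = []
        for label in labels:
            mesh = tessellate_label(solid, label, pitch=pitch)
            if mesh is None:
                continue
            out = path / f"{label}.stl"
            mesh.export(out)
            written.append(out)
        return written
    if fmt == "vtk":
        ids, (xs, ys, zs) = voxelize(solid, pitch)
        path.parent.mkdir(parents=True, exist_ok=True)
        write_vtk_unstructured(path, ids, (xs, ys, zs), pitch)
        return [path]
    raise ValueError(f"unsupported mesh format {fmt!r}; use 'stl' or 'vtk'")


def write_vtk_unstructured(
    path: str | Path,
    ids: np.ndarray,
    axes: tuple[np.ndarray, np.ndarray, np.ndarray],
    pitch: float,
) -> None:
    """Write non-void voxels as hexahedral cells in VTK legacy ASCII format."""
    xs, ys, zs = axes
    ii, jj, kk = np.nonzero(ids > 0)
    mats = ids[ii, jj, kk]
    # corner-point index grid; deduplicate shared corners
    corners = np.empty((ii.size, 8), dtype=np.int64)
    nX, nY = xs.size + 1, ys.size + 1
    # VTK_HEXAHEDRON ordering: bottom face CCW then top face CCW
    offs = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)]
    for c, (di, dj, dk) in enumerate(offs):
        corners[:, c] = (ii + di) + (jj + dj) * nX + (kk + dk) * nX * nY
    uniq, inv = np.unique(corners, return_inverse=True)
    conn = inv.reshape(corners.shape)
    pi = uniq % nX
    pj = (uniq // nX) % nY
    pk = uniq // (nX * nY)
    h = 0.5 * pitch
    px = xs[0] - h + pi * pitch
    py = ys[0] - h + pj * pitch
    pz = zs[0] - h + pk * pitch
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nlesionlab labeled voxel mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {uniq.size} float\n")
        np.savetxt(f, np.column_stack([px, py, pz]), fmt="%.6g")
        f.write(f"CELLS {conn.shape[0]} {conn.shape[0] * 9}\n")
        np.savetxt(f, np.column_stack([np.full(conn.shape[0], 8), conn]), fmt="%d")
        f.write(f"CELL_TYPES {conn.shape[0]}\n")
        np.savetxt(f, np.full(conn.shape[0], 12), fmt="%d")
        f.write(f"CELL_DATA {conn.shape[0]}\nSCALARS material_id int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mats, fmt="%d")
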