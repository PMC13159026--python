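"""File formats: NIfTI volumes, landmark/plane JSON, OFF/VTK mesh export."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .meshing import CCMesh
from .midplane import LabelMap, Plane


def load_labelmap(path) -> LabelMap:
    img = nib.load(str(path))
    return LabelMap(voxels=np.asarray(img.dataobj).astype(np.int32),
                    affine=img.affine)


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def save_volume(path, data: np.ndarray, affine: np.ndarray | None = None):
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))


def load_landmarks(path) -> dict:
    """JSON with keys "AC" and "PC" (2 or 3 floats, mm)."""
    with open(path) as fh:
        data = json.load(fh)
    out = {}
    for key in ("AC", "PC"):
        if key not in data:
            raise ValueError(f"landmark file missing key '{key}'")
        out[key] = np.asarray(data[key], dtype=float)
    return out


def save_landmarks(path, ac, pc):
    with open(path, "w") as fh:
        json.dump({"AC": np.asarray(ac, dtype=float).tolist(),
                   "PC": np.asarray(pc, dtype=float).tolist()}, fh, indent=2)


def save_plane(path, plane: Plane):
    """Plane serialized as its 4x4 frame matrix (row-major)."""
    with open(path, "w") as fh:
        json.dump({"frame": plane.frame_matrix().tolist()}, fh, indent=2)


def load_plane(path) -> Plane:
    with open(path) as fh:
        data = json.load(fh)
    return Plane.from_frame_matrix(np.asarray(data["frame"], dtype=float))


def save_mesh_off(path, mesh: CCMesh):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} 0\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def load_mesh_off(path) -> CCMesh:
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nt = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nt):
        k = int(tokens[pos])
        tris.append([int(x) for x in tokens[pos + 1:pos + 1 + k]])
        pos += k + 1
    tris = np.asarray(tris, dtype=int)
    mesh = CCMesh(vertices=verts[:, :2], triangles=tris,
                  boundary=_boundary_loop(verts[:, :2], tris))
    return mesh


def _boundary_loop(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Recover the ordered boundary loop from triangle connectivity."""
    count: dict[tuple[int, int], int] = {}
    directed: dict[int, int] = {}
    for tri in triangles:
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            count[(min(a, b), max(a, b))] = count.get((min(a, b), max(a, b)),
                                                      0) + 1
    for tri in triangles:
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            if count[(min(a, b), max(a, b))] == 1:
                directed[a] = b
    if not directed:
        raise ValueError("mesh has no boundary")
    start = next(iter(directed))
    loop = [start]
    cur = directed[start]
    while cur != start:
        loop.append(cur)
        cur = directed[cur]
        if len(loop) > len(vertices):
            raise ValueError("boundary loop does not close")
    return np.asarray(loop, dtype=int)


def save_mesh_vtk(path, mesh: CCMesh, point_data: dict | None = None,
                  cell_data: dict | None = None):
    """ASCII legacy VTK polydata with optional per-vertex/per-face scalars."""
    lines = ["# vtk DataFile Version 3.0", "ccmorph mesh", "ASCII",
             "DATASET POLYDATA", f"POINTS {mesh.n_vertices} float"]
    for p in mesh.vertices:
        lines.append(f"{p[0]:.9g} {p[1]:.9g} 0")
    nt = len(mesh.triangles)
    lines.append(f"POLYGONS {nt} {4 * nt}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_vertices}")
        for name, values in point_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(values, dtype=float))
    if cell_data:
        lines.append(f"CELL_DATA {nt}")
        for name, values in cell_data.items():
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in np.asarray(values, dtype=float))
    Path(path).write_text("\n".join(lines) + "\n")


def save_polylines_vtk(path, polylines: list):
    """Polylines (list of (m, 2) arrays) as VTK LINES."""
    pls = [np.asarray(p, dtype=float) for p in polylines if p is not None
           and len(p) >= 2]
    npts = sum(len(p) for p in pls)
    lines = ["# vtk DataFile Version 3.0", "ccmorph polylines", "ASCII",
             "DATASET POLYDATA", f"POINTS {npts} float"]
    for p in pls:
        for q in p:
            lines.append(f"{q[0]:.9g} {q[1]:.9g} 0")
    size = sum(len(p) + 1 for p in pls)
    lines.append(f"LINES {len(pls)} {size}")
    offset = 0
    for p in pls:
        lines.append(" ".join([str(len(p))]
                              + [str(offset + i) for i in range(len(p))]))
        offset += len(p)
    Path(path).write_text("\n".join(lines) + "\n")


def save_contour_csv(path, contour_vertices: np.ndarray):
    arr = np.asarray(contour_vertices, dtype=float)
    header = "a_mm,s_mm"
    np.savetxt(str(path), arr, delimiter=",", header=header, comments="")


def save_profile_tsv(path, positions, thickness):
    arr = np.column_stack([positions, thickness])
    np.savetxt(str(path), arr, delimiter="\t", header="s\tthickness_mm",
               comments="")
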