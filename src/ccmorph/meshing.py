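"""Binary mid-sagittal mask -> sub-voxel triangle mesh with labeled boundary.

The 2D frame is (a, s): first coordinate anterior-positive, second
superior-positive, in mm.  Mask arrays are indexed ``mask[i, j]`` with
``i`` along a and ``j`` along s; voxel centers sit at integer indices, so
world coordinates are ``index * resolution`` (plus an optional origin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .geometry import (chaikin_smooth, ensure_ccw, polyline_length,
                       shoelace_area, triangle_areas)
from .triangulate import TriangulationError, triangulate_polygon

INFERIOR = 0
SUPERIOR = 1


class MeshingError(RuntimeError):
    pass


@dataclass
class Contour2D:
    """Closed simple polygon in the mid-sagittal frame (CCW, mm)."""

    vertices: np.ndarray

    def __post_init__(self):
        self.vertices = ensure_ccw(np.asarray(self.vertices, dtype=float))
        if len(self.vertices) < 3:
            raise MeshingError("contour needs at least 3 vertices")

    @property
    def area(self) -> float:
        return shoelace_area(self.vertices)

    @property
    def perimeter(self) -> float:
        closed = np.vstack([self.vertices, self.vertices[:1]])
        return polyline_length(closed)


@dataclass
class CCMesh:
    """Triangle mesh of the mid-sagittal CC cross-section.

    ``boundary`` is the ordered CCW vertex loop (indices into ``vertices``);
    ``chain_labels[k]`` labels the boundary edge from ``boundary[k]`` to
    ``boundary[k+1]`` as INFERIOR (0) or SUPERIOR (1).  ``endpoints`` are
    (anterior, posterior) vertex indices where the two chains meet.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    boundary: np.ndarray
    chain_labels: np.ndarray | None = None
    endpoints: tuple[int, int] | None = None
    resolution: float | None = field(default=None)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def boundary_points(self) -> np.ndarray:
        return self.vertices[self.boundary]

    def triangle_areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.triangles)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def perimeter(self) -> float:
        loop = np.vstack([self.boundary_points, self.boundary_points[:1]])
        return polyline_length(loop)

    def boundary_edge_labels(self) -> dict[tuple[int, int], int]:
        """Map (sorted vertex pair) -> chain label for all boundary edges."""
        if self.chain_labels is None:
            raise MeshingError("boundary chains not labeled yet")
        out = {}
        nb = len(self.boundary)
        for k in range(nb):
            a = int(self.boundary[k])
            b = int(self.boundary[(k + 1) % nb])
            out[(min(a, b), max(a, b))] = int(self.chain_labels[k])
        return out


def mask_to_contour(mask: np.ndarray, resolution: float = 1.0,
                    origin=(0.0, 0.0), min_area_mm2: float = 0.0,
                    smooth_iters: int = 2) -> Contour2D:
    """Extract the iso-0.5 sub-voxel contour of a binary mask.

    Marching squares on the bilinearly interpolated mask; when several
    closed contours exist, the one enclosing the largest area wins (holes
    and stray islands are discarded).  ``smooth_iters`` rounds of Chaikin
    corner cutting remove the staircase pattern binary masks produce
    (set 0 to keep the raw iso contour).
    """
    mask = np.asarray(mask)
    if mask.sum() == 0:
        raise MeshingError("mask is empty")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise MeshingError("no contour found at iso level 0.5")
    best, best_area = None, -np.inf
    for c in contours:
        area = abs(shoelace_area(c))
        if area > best_area:
            best, best_area = c, area
    best_area_mm2 = best_area * resolution ** 2
    if best_area_mm2 < min_area_mm2:
        raise MeshingError(
            f"largest component area {best_area_mm2:.3f} mm^2 below minimum "
            f"{min_area_mm2:.3f} mm^2")
    # drop duplicated closing vertex, shift off the padding, scale to mm
    verts = best[:-1] if np.allclose(best[0], best[-1]) else best
    verts = (verts - 1.0) * resolution + np.asarray(origin, dtype=float)
    if smooth_iters > 0:
        verts = chaikin_smooth(verts, smooth_iters)
    return Contour2D(verts)


def contour_to_mesh(contour: Contour2D, max_edge_mm: float = 1.0) -> CCMesh:
    """Triangulate the interior of a contour into a conforming mesh."""
    try:
        points, tris, nb = triangulate_polygon(contour.vertices, max_edge_mm)
    except TriangulationError as exc:
        raise MeshingError(str(exc)) from exc
    return CCMesh(vertices=points, triangles=tris,
                  boundary=np.arange(nb))


def find_endpoints(mesh: CCMesh, ac, pc) -> tuple[int, int]:
    """Anterior/posterior endpoint vertices: nearest boundary vertex to the
    AC and PC landmarks respectively."""
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    bp = mesh.boundary_points
    ia = int(np.argmin(np.linalg.norm(bp - ac, axis=1)))
    ip = int(np.argmin(np.linalg.norm(bp - pc, axis=1)))
    anterior = int(mesh.boundary[ia])
    posterior = int(mesh.boundary[ip])
    if anterior == posterior:
        raise MeshingError("anterior and posterior endpoints coincide")
    return anterior, posterior


def partition_boundary(mesh: CCMesh, endpoints: tuple[int, int]) -> np.ndarray:
    """Label each boundary edge INFERIOR or SUPERIOR.

    The loop is split into the two open chains between the endpoints; the
    chain with the lower mean superior coordinate becomes INFERIOR.
    Returns the per-edge label array and stores it on the mesh.
    """
    anterior, posterior = endpoints
    loop = list(mesh.boundary)
    try:
        ka = loop.index(anterior)
        kp = loop.index(posterior)
    except ValueError as exc:
        raise MeshingError("endpoint not on boundary loop") from exc
    nb = len(loop)
    if (ka - kp) % nb in (1, nb - 1):
        raise MeshingError("endpoints are adjacent on the boundary loop")

    # edges ka..kp-1 form chain A, kp..ka-1 form chain B (cyclic)
    idx_a = [(ka + t) % nb for t in range((kp - ka) % nb)]
    idx_b = [(kp + t) % nb for t in range((ka - kp) % nb)]

    def mean_s(edge_idx):
        ss = []
        for k in edge_idx:
            v0 = mesh.boundary[k]
            v1 = mesh.boundary[(k + 1) % nb]
            ss.append(0.5 * (mesh.vertices[v0, 1] + mesh.vertices[v1, 1]))
        return float(np.mean(ss))

    labels = np.empty(nb, dtype=int)
    if mean_s(idx_a) < mean_s(idx_b):
        labels[idx_a] = INFERIOR
        labels[idx_b] = SUPERIOR
    else:
        labels[idx_a] = SUPERIOR
        labels[idx_b] = INFERIOR
    mesh.chain_labels = labels
    mesh.endpoints = (anterior, posterior)
    return labels


def build_cc_mesh(mask: np.ndarray, resolution: float, ac, pc,
                  max_edge_mm: float = 1.0, origin=(0.0, 0.0),
                  min_area_mm2: float = 0.0, smooth_iters: int = 2) -> CCMesh:
    """Mask + landmarks -> fully labeled CCMesh (convenience wrapper)."""
    contour = mask_to_contour(mask, resolution, origin=origin,
                              min_area_mm2=min_area_mm2,
                              smooth_iters=smooth_iters)
    mesh = contour_to_mesh(contour, max_edge_mm)
    mesh.resolution = resolution
    endpoints = find_endpoints(mesh, ac, pc)
    partition_boundary(mesh, endpoints)
    return mesh


def mesh_from_contour(contour: Contour2D, ac, pc,
                      max_edge_mm: float = 1.0) -> CCMesh:
    """Analytic-contour variant of :func:`build_cc_mesh` (no rasterization)."""
    mesh = contour_to_mesh(contour, max_edge_mm)
    endpoints = find_endpoints(mesh, ac, pc)
    partition_boundary(mesh, endpoints)
    return mesh
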