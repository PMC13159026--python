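"""Conforming triangulation of simple polygons.

Strategy: densify the polygon boundary to the target edge length, seed the
interior with a hexagonal point lattice kept clear of the boundary, build an
unconstrained Delaunay triangulation (scipy/Qhull) and keep the triangles
whose centroid falls inside the polygon.  Boundary conformity is then
*verified*: every polygon segment must appear as a mesh edge.  Missing
segments are bisected and the triangulation rebuilt — the classical
conforming-Delaunay refinement loop, which terminates because segments
shrink geometrically.

The resulting mesh partitions the polygon exactly (mesh area == shoelace
area up to floating point), has Delaunay quality, and its boundary loop is
the densified input polygon.
"""

from __future__ import annotations

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .geometry import ensure_ccw, triangle_areas


class TriangulationError(RuntimeError):
    pass


def _densify_segments(vertices: np.ndarray, max_edge: float) -> np.ndarray:
    """Split each polygon edge into pieces no longer than max_edge."""
    out = []
    n = len(vertices)
    for i in range(n):
        a = vertices[i]
        b = vertices[(i + 1) % n]
        length = np.linalg.norm(b - a)
        k = max(int(np.ceil(length / max_edge)), 1)
        for t in range(k):
            out.append(a + (b - a) * (t / k))
    return np.asarray(out)


def _hex_lattice(bounds, spacing: float) -> np.ndarray:
    x0, y0, x1, y1 = bounds
    dy = spacing * np.sqrt(3) / 2
    rows = []
    y = y0
    row = 0
    while y <= y1:
        xs = np.arange(x0 + (spacing / 2 if row % 2 else 0.0), x1 + 1e-9,
                       spacing)
        if len(xs):
            rows.append(np.column_stack([xs, np.full(len(xs), y)]))
        y += dy
        row += 1
    if not rows:
        return np.zeros((0, 2))
    return np.vstack(rows)


def _remove_slivers(points: np.ndarray, simplices: np.ndarray,
                    rel_tol: float = 1e-7, max_rounds: int = 500) -> np.ndarray:
    """Flip away (near-)zero-area triangles.

    Qhull emits degenerate simplices for exactly collinear point triples
    (densified points along straight polygon chords).  Each sliver is
    repaired by flipping its longest edge against the neighboring
    triangle — an exact, area- and boundary-preserving local operation.
    """
    simplices = simplices.copy()
    for _ in range(max_rounds):
        areas = np.abs(triangle_areas(points, simplices))
        thresh = rel_tol * np.median(areas)
        bad = np.where(areas < thresh)[0]
        if len(bad) == 0:
            return simplices
        edge_map: dict[tuple[int, int], list[int]] = {}
        for t, tri in enumerate(simplices):
            for i in range(3):
                a, b = int(tri[i]), int(tri[(i + 1) % 3])
                edge_map.setdefault((min(a, b), max(a, b)), []).append(t)
        t = int(bad[0])
        tri = simplices[t]
        p = points[tri]
        lengths = [np.linalg.norm(p[(i + 1) % 3] - p[(i + 2) % 3])
                   for i in range(3)]
        apex = int(np.argmax(lengths))          # vertex opposite longest edge
        b_mid = int(tri[apex])
        a, c = int(tri[(apex + 1) % 3]), int(tri[(apex + 2) % 3])
        key = (min(a, c), max(a, c))
        neighbors = [x for x in edge_map.get(key, []) if x != t]
        if not neighbors:
            # flat sliver lying on the boundary chord: its short edges are
            # backed by interior triangles, so it can simply be dropped
            short_ok = all(
                len([x for x in edge_map.get((min(e), max(e)), []) if x != t])
                == 1
                for e in ((a, b_mid), (b_mid, c)))
            if not short_ok:
                raise TriangulationError(
                    "degenerate boundary triangle cannot be repaired")
            simplices = np.delete(simplices, t, axis=0)
            continue
        t2 = neighbors[0]
        d = next(int(x) for x in simplices[t2] if int(x) not in (a, c))
        for tt, new in ((t, (a, b_mid, d)), (t2, (b_mid, c, d))):
            tri_new = np.array(new)
            if triangle_areas(points, tri_new[None])[0] < 0:
                tri_new = tri_new[::-1]
            simplices[tt] = tri_new
    raise TriangulationError("sliver removal did not converge")


def triangulate_polygon(vertices: np.ndarray, max_edge: float,
                        max_boundary_rounds: int = 8):
    """Triangulate the interior of a simple polygon.

    Parameters
    ----------
    vertices:
        Polygon vertices (closed implicitly), any orientation.
    max_edge:
        Target upper bound for edge lengths (boundary edges are split to
        respect it; interior lattice spacing matches it).

    Returns
    -------
    (points, triangles, n_boundary):
        ``points[:n_boundary]`` is the densified boundary loop in CCW
        order; triangles are index triples, all positively oriented.
    """
    verts = ensure_ccw(np.asarray(vertices, dtype=float))
    if len(verts) < 3:
        raise TriangulationError("polygon needs at least 3 vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise TriangulationError(
            f"polygon is not simple/valid: {shapely.is_valid_reason(poly)}")

    boundary = _densify_segments(verts, max_edge)

    # interior lattice, kept clear of the boundary
    spacing = max_edge * 0.9
    lattice = _hex_lattice(poly.bounds, spacing)
    if len(lattice):
        inside = shapely.contains_xy(poly, lattice[:, 0], lattice[:, 1])
        lattice = lattice[inside]
    if len(lattice):
        ring = poly.exterior
        dist = shapely.distance(shapely.points(lattice), ring)
        lattice = lattice[dist > 0.55 * spacing]

    for _ in range(max_boundary_rounds):
        nb = len(boundary)
        points = np.vstack([boundary, lattice]) if len(lattice) else boundary
        tri = Delaunay(points)
        simplices = tri.simplices

        cent = points[simplices].mean(axis=1)
        keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        simplices = simplices[keep]
        if len(simplices) == 0:
            raise TriangulationError("no interior triangles found")

        # verify every boundary segment is a mesh edge
        edges = set()
        for t in simplices:
            for a, b in ((t[0], t[1]), (t[1], t[2]), (t[2], t[0])):
                edges.add((min(a, b), max(a, b)))
        missing = [i for i in range(nb)
                   if (min(i, (i + 1) % nb), max(i, (i + 1) % nb)) not in edges]
        if not missing:
            areas = triangle_areas(points, simplices)
            flip = areas < 0
            simplices[flip] = simplices[flip][:, ::-1]
            simplices = _remove_slivers(points, simplices)
            return points, simplices, nb

        # bisect missing segments and retry
        new_boundary = []
        missing_set = set(missing)
        for i in range(nb):
            new_boundary.append(boundary[i])
            if i in missing_set:
                mid = 0.5 * (boundary[i] + boundary[(i + 1) % nb])
                new_boundary.append(mid)
        boundary = np.asarray(new_boundary)

    raise TriangulationError(
        "boundary recovery did not converge (polygon too thin or degenerate)")
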