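"""Small 2D geometry helpers shared across the pipeline.

All coordinates are in the mid-sagittal frame: first axis ``a`` (anterior
positive), second axis ``s`` (superior positive), units mm.
"""

from __future__ import annotations

import numpy as np


def shoelace_area(vertices: np.ndarray) -> float:
    """Signed area of a closed polygon (positive for counter-clockwise)."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_length(points: np.ndarray) -> float:
    """Total length of an open polyline (sum of segment lengths)."""
    p = np.asarray(points, dtype=float)
    if len(p) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    p = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at (approximately) uniform arc-length spacing.

    The first and last points are preserved exactly.  ``step`` is an upper
    bound; the actual spacing divides the total length evenly.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        return p.copy()
    t = cumulative_arclength(p)
    total = t[-1]
    if total <= 0:
        return p[[0, -1]].copy()
    n = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n + 1)
    out = np.empty((n + 1, p.shape[1]))
    for d in range(p.shape[1]):
        out[:, d] = np.interp(targets, t, p[:, d])
    return out


def interp_along_polyline(points: np.ndarray, values: np.ndarray,
                          arclens: np.ndarray) -> np.ndarray:
    """Linearly interpolate per-vertex values at given arc-length positions."""
    t = cumulative_arclength(points)
    return np.interp(arclens, t, values)


def point_at_arclength(points: np.ndarray, arclen: float) -> np.ndarray:
    t = cumulative_arclength(points)
    a = np.clip(arclen, 0.0, t[-1])
    out = np.empty(points.shape[1])
    for d in range(points.shape[1]):
        out[d] = np.interp(a, t, points[:, d])
    return out


def turning_angles(points: np.ndarray) -> np.ndarray:
    """Signed turning angle (radians) at each interior vertex of a polyline."""
    p = np.asarray(points, dtype=float)
    d = np.diff(p, axis=0)
    keep = np.linalg.norm(d, axis=1) > 1e-12
    d = d[keep]
    if len(d) < 2:
        return np.zeros(0)
    a = np.arctan2(d[:, 1], d[:, 0])
    da = np.diff(a)
    # wrap into (-pi, pi]
    return (da + np.pi) % (2 * np.pi) - np.pi


def chaikin_smooth(vertices: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Chaikin corner cutting on a closed polygon.

    Each iteration replaces every edge by its 1/4 and 3/4 points,
    converging toward a quadratic B-spline; removes rasterization
    staircase while preserving shape at the scale of a few segments.
    """
    v = np.asarray(vertices, dtype=float)
    for _ in range(iterations):
        nxt = np.roll(v, -1, axis=0)
        q = 0.75 * v + 0.25 * nxt
        r = 0.25 * v + 0.75 * nxt
        v = np.empty((2 * len(v), 2))
        v[0::2] = q
        v[1::2] = r
    return v


def ensure_ccw(vertices: np.ndarray) -> np.ndarray:
    """Return polygon vertices in counter-clockwise orientation."""
    v = np.asarray(vertices, dtype=float)
    if shoelace_area(v) < 0:
        return v[::-1].copy()
    return v


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed areas of mesh triangles (positive = counter-clockwise)."""
    p = vertices[triangles]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    return 0.5 * (e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0])


def clip_polygon_halfplane(poly: np.ndarray, normal: np.ndarray,
                           offset: float) -> np.ndarray:
    """Clip a convex polygon to the half-plane ``normal . p >= offset``.

    Sutherland-Hodgman; returns the clipped polygon (possibly empty).
    """
    out: list[np.ndarray] = []
    n = len(poly)
    d = poly @ np.asarray(normal, dtype=float) - offset
    for i in range(n):
        j = (i + 1) % n
        di, dj = d[i], d[j]
        if di >= 0:
            out.append(poly[i])
        if (di > 0 and dj < 0) or (di < 0 and dj > 0):
            t = di / (di - dj)
            out.append(poly[i] + t * (poly[j] - poly[i]))
    if not out:
        return np.zeros((0, 2))
    return np.asarray(out)


def rigid_2d(angle: float, translation) -> np.ndarray:
    """3x3 homogeneous 2D rigid transform (rotation then translation)."""
    c, s = np.cos(angle), np.sin(angle)
    m = np.eye(3)
    m[:2, :2] = [[c, -s], [s, c]]
    m[:2, 2] = translation
    return m


def apply_2d(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, dtype=float)
    return p @ matrix[:2, :2].T + matrix[:2, 2]
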