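"""Parametric sub-segmentation of the CC mesh.

Five schemes are provided:

* ``anchor_line`` — cuts orthogonal to an anchor line (through the CC's
  extremal points, Witelson-style, or through the AC/PC landmarks);
* ``eigendirection`` — equal-width cuts along the first principal axis of
  the area-weighted triangle centroids;
* ``rays`` — equally spaced rays from the midpoint of the inferior edge of
  the bounding rectangle;
* ``arclength`` — the perpendicular scheme: cuts along conjugate-potential
  level paths anchored at arc-length fractions of the intercallosal line.

All schemes split crossing triangles exactly (half-plane clipping for
straight cuts, linear level interpolation for the level-path cuts), so
region areas always sum to the mesh area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import clip_polygon_halfplane, point_at_arclength
from .laplace import IntercallosalLine
from .meshing import CCMesh

WITELSON_FRACTIONS = (1 / 3, 1 / 2, 2 / 3, 4 / 5)
HOFER_FRAHM_FRACTIONS = (1 / 6, 1 / 2, 2 / 3, 3 / 4)


class SubsegError(RuntimeError):
    pass


@dataclass
class SubsegResult:
    face_labels: np.ndarray     # region index per triangle (by centroid)
    region_areas: np.ndarray    # mm^2, exact split
    n_regions: int
    scheme: str = ""
    cut_geometry: list = field(default_factory=list)


def _check_fractions(fractions):
    f = np.asarray(fractions, dtype=float)
    if len(f) == 0 or np.any(f <= 0) or np.any(f >= 1) or np.any(np.diff(f) <= 0):
        raise SubsegError("fractions must be strictly increasing in (0,1)")
    return f


def _bands_from_scalar(mesh: CCMesh, vertex_scalar: np.ndarray,
                       cuts: np.ndarray, scheme: str) -> SubsegResult:
    """Partition by a per-vertex scalar with exact triangle splitting.

    Level sets of the linearly interpolated scalar are straight segments
    inside each triangle, so clipping against successive thresholds is an
    exact area split.
    """
    tris = mesh.triangles
    vals = vertex_scalar[tris]
    n_regions = len(cuts) + 1
    areas = np.zeros(n_regions)
    edges = np.concatenate([[-np.inf], cuts, [np.inf]])
    cent_val = vals.mean(axis=1)
    face_labels = np.searchsorted(cuts, cent_val)
    for t in range(len(tris)):
        lo, hi = vals[t].min(), vals[t].max()
        first = np.searchsorted(cuts, lo)
        last = np.searchsorted(cuts, hi)
        p = mesh.vertices[tris[t]]
        if first == last:
            areas[first] += _poly_area(p)
            continue
        # split the triangle across the straddled thresholds in scalar space
        for r in range(first, last + 1):
            piece = _clip_triangle_scalar(p, vals[t], edges[r], edges[r + 1])
            areas[r] += piece
    return SubsegResult(face_labels=face_labels, region_areas=areas,
                        n_regions=n_regions, scheme=scheme)


def _poly_area(poly: np.ndarray) -> float:
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _clip_triangle_scalar(p: np.ndarray, v: np.ndarray, lo: float,
                          hi: float) -> float:
    """Area of {x in triangle : lo <= scalar(x) < hi} for linear scalar."""
    # clip in (x, y, scalar) space: the scalar is linear, so the region is
    # the triangle clipped by two parallel lines in the plane
    poly = p
    g = _linear_gradient(p, v)
    ng = np.linalg.norm(g)
    if ng < 1e-15:
        return _poly_area(p) if lo <= v.mean() < hi else 0.0
    # scalar(x) = v0 + g.(x - p0)
    c0 = v[0] - g @ p[0]
    if np.isfinite(lo):
        poly = clip_polygon_halfplane(poly, g, lo - c0)
    if len(poly) < 3:
        return 0.0
    if np.isfinite(hi):
        poly = clip_polygon_halfplane(poly, -g, -(hi - c0))
    return _poly_area(poly)


def _linear_gradient(p: np.ndarray, v: np.ndarray) -> np.ndarray:
    m = np.column_stack([p[1] - p[0], p[2] - p[0]]).T
    try:
        return np.linalg.solve(m, v[1:] - v[0])
    except np.linalg.LinAlgError:
        return np.zeros(2)


# ---------------------------------------------------------------------------

def subsegment_anchor_line(mesh: CCMesh, anchor_a, anchor_b,
                           fractions=HOFER_FRAHM_FRACTIONS) -> SubsegResult:
    """Cuts orthogonal to the anchor line at normalized projections."""
    fractions = _check_fractions(fractions)
    a = np.asarray(anchor_a, dtype=float)
    b = np.asarray(anchor_b, dtype=float)
    d = b - a
    if np.linalg.norm(d) < 1e-9:
        raise SubsegError("anchor points coincide")
    d = d / np.linalg.norm(d)
    proj = (mesh.vertices - a) @ d
    lo, hi = proj.min(), proj.max()
    scalar = (proj - lo) / (hi - lo)
    res = _bands_from_scalar(mesh, scalar, fractions, "anchor_line")
    res.cut_geometry = [("line", a + (lo + f * (hi - lo)) * d, d)
                        for f in fractions]
    return res


def subsegment_eigendirection(mesh: CCMesh, n_regions: int = 5
                              ) -> SubsegResult:
    """Equal-width cuts along the first principal component of the
    area-weighted triangle centroids."""
    if n_regions < 2:
        raise SubsegError("need at least 2 regions")
    areas = np.abs(mesh.triangle_areas())
    cent = mesh.vertices[mesh.triangles].mean(axis=1)
    mu = np.average(cent, axis=0, weights=areas)
    x = cent - mu
    cov = (x * areas[:, None]).T @ x / areas.sum()
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] > 0.95 * evals[1]:
        raise SubsegError("shape is isotropic; principal axis ambiguous")
    axis = evecs[:, -1]
    proj = (mesh.vertices - mu) @ axis
    scalar = (proj - proj.min()) / (proj.max() - proj.min())
    cuts = np.arange(1, n_regions) / n_regions
    res = _bands_from_scalar(mesh, scalar, cuts, "eigendirection")
    return _anterior_first(res, mesh, scalar)


def subsegment_rays(mesh: CCMesh, n_rays: int = 3) -> SubsegResult:
    """Angular sectors from the midpoint of the bounding box's inferior
    edge; n_rays rays at equal angles over (0, pi) give n_rays+1 sectors."""
    if n_rays < 1:
        raise SubsegError("need at least one ray")
    pts = mesh.vertices
    x0, y0 = pts.min(axis=0)
    x1, _ = pts.max(axis=0)
    origin = np.array([(x0 + x1) / 2, y0])
    rel = mesh.vertices - origin
    if np.any(np.linalg.norm(rel, axis=1) < 1e-9):
        raise SubsegError("ray origin lies on the mesh")
    # angle from +a axis, in [0, pi] for points above the origin
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    cut_angles = np.arange(1, n_rays + 1) * np.pi / (n_rays + 1)
    # region 0 is the anterior sector (angle near 0 = +a side)
    res = _bands_from_scalar(mesh, ang, cut_angles, "rays")
    res.cut_geometry = [("ray", origin, np.array([np.cos(t), np.sin(t)]))
                        for t in cut_angles]
    return res


def subsegment_arclength(mesh: CCMesh, v: np.ndarray,
                         line: IntercallosalLine,
                         fractions=HOFER_FRAHM_FRACTIONS) -> SubsegResult:
    """The perpendicular scheme: cuts along v-level paths through the
    points at the given arc-length fractions of the intercallosal line."""
    fractions = _check_fractions(fractions)
    if line.values_v is None:
        raise SubsegError("line carries no conjugate-potential values")
    total = line.length
    al = line.arc_length
    v_cuts = np.array([float(np.interp(f * total, al, line.values_v))
                       for f in fractions])
    if np.any(np.diff(v_cuts) <= 0):
        raise SubsegError("conjugate potential not monotone along the line")
    res = _bands_from_scalar(mesh, v, v_cuts, "arclength")
    res.cut_geometry = [("level", float(c)) for c in v_cuts]
    return res


def _anterior_first(res: SubsegResult, mesh: CCMesh,
                    scalar: np.ndarray) -> SubsegResult:
    """Renumber regions so region 0 is the most anterior."""
    cent = mesh.vertices[mesh.triangles].mean(axis=1)
    order = np.argsort([cent[res.face_labels == r, 0].mean()
                        if np.any(res.face_labels == r) else np.inf
                        for r in range(res.n_regions)])[::-1]
    if np.all(order == np.arange(res.n_regions)):
        return res
    remap = np.empty(res.n_regions, dtype=int)
    remap[order] = np.arange(res.n_regions)
    res.face_labels = remap[res.face_labels]
    res.region_areas = res.region_areas[order]
    return res


SCHEMES = ("witelson", "hofer-frahm", "eigen", "rays", "arclength")


def subsegment(mesh: CCMesh, scheme: str, v=None, line=None, ac=None, pc=None,
               fractions=None, n_regions: int = 5, n_rays: int = 3
               ) -> SubsegResult:
    """Dispatch a named scheme with its conventional defaults."""
    scheme = scheme.lower()
    if scheme == "witelson":
        f = fractions if fractions is not None else WITELSON_FRACTIONS
        a, b = _extremal_anchor(mesh)
        return subsegment_anchor_line(mesh, a, b, f)
    if scheme in ("hofer-frahm", "hofer_frahm"):
        f = fractions if fractions is not None else HOFER_FRAHM_FRACTIONS
        a, b = _extremal_anchor(mesh)
        return subsegment_anchor_line(mesh, a, b, f)
    if scheme in ("jancke", "ac-pc"):
        if ac is None or pc is None:
            raise SubsegError("AC/PC landmarks required for this scheme")
        f = fractions if fractions is not None else WITELSON_FRACTIONS
        return subsegment_anchor_line(mesh, ac, pc, f)
    if scheme == "eigen":
        return subsegment_eigendirection(mesh, n_regions)
    if scheme == "rays":
        return subsegment_rays(mesh, n_rays)
    if scheme == "arclength":
        if v is None or line is None:
            raise SubsegError("arclength scheme needs the conjugate "
                              "potential and the intercallosal line")
        f = fractions if fractions is not None else HOFER_FRAHM_FRACTIONS
        return subsegment_arclength(mesh, v, line, f)
    raise SubsegError(f"unknown scheme '{scheme}'")


def _extremal_anchor(mesh: CCMesh):
    """Most anterior and most posterior boundary points (anchor runs
    anterior -> posterior so fractions are measured from the anterior end)."""
    a = mesh.vertices[:, 0]
    return (mesh.vertices[int(np.argmax(a))].copy(),
            mesh.vertices[int(np.argmin(a))].copy())
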