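"""Harmonic thickness machinery on the CC mesh.

Pipeline: solve the Laplace equation with opposite unit charges on the
inferior/superior boundary chains (linear finite elements, cotangent
weights), build the conjugate potential whose gradient is the 90-degree
rotation of the primary gradient, extract the intercallosal line as the
zero level set of the primary potential, and measure thickness as the
length of conjugate-potential level paths running from the inferior to the
superior chain.

Boundary conditions: chain vertices carry Dirichlet values -1 (inferior)
and +1 (superior).  Ribbon-like shapes whose ends are cut off ("end caps")
are detected by walking the boundary from each endpoint until the
cumulative turning angle reveals a corner; the cap interior is left free
(natural/no-flux condition), which makes the solver exact on rectangles
and annulus sectors where the analytic solution has no flux through the
caps.  When no cap exists (tapered tip), the endpoint vertex is clamped to
0 so the zero level set terminates there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial import cKDTree

from .geometry import (cumulative_arclength, point_at_arclength,
                       polyline_length, resample_polyline, turning_angles)
from .meshing import INFERIOR, SUPERIOR, CCMesh

__all__ = [
    "LaplaceField", "IntercallosalLine", "ThicknessProfile",
    "solve_laplace", "conjugate_potential", "extract_level_set",
    "intercallosal_line", "thickness_profile", "line_curvature",
    "line_length", "streamline_thickness",
]


class LaplaceError(RuntimeError):
    pass


@dataclass
class LaplaceField:
    u: np.ndarray
    v: np.ndarray | None = None


@dataclass
class IntercallosalLine:
    """Zero level set of u, oriented anterior -> posterior."""

    points: np.ndarray                       # (m, 2) polyline, mm
    values_v: np.ndarray | None = None       # conjugate potential per point
    snapped: tuple[bool, bool] = (False, False)

    @property
    def arc_length(self) -> np.ndarray:
        return cumulative_arclength(self.points)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    @property
    def s(self) -> np.ndarray:
        al = self.arc_length
        return al / al[-1]


@dataclass
class ThicknessProfile:
    positions: np.ndarray                    # s_i in (0, 1)
    thickness: np.ndarray                    # mm; NaN where flagged missing
    level_paths: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.thickness)


# ---------------------------------------------------------------------------
# finite elements

def p1_gradients(mesh: CCMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle shape-function gradients and areas.

    Returns (grads, areas) with grads[t, i] the gradient of the hat
    function of local vertex i on triangle t.
    """
    p = mesh.vertices[mesh.triangles]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    if np.any(areas <= 0):
        bad = np.where(areas <= 0)[0]
        raise LaplaceError(f"degenerate/inverted triangles: {bad[:10].tolist()}")
    grads = np.empty((len(p), 3, 2))
    for i in range(3):
        e = p[:, (i + 2) % 3] - p[:, (i + 1) % 3]   # opposite edge
        grads[:, i, 0] = -e[:, 1]
        grads[:, i, 1] = e[:, 0]
    grads /= (2 * areas)[:, None, None]
    return grads, areas


def stiffness_matrix(mesh: CCMesh) -> sparse.csr_matrix:
    """P1 cotangent stiffness matrix (integral of grad phi_i . grad phi_j)."""
    grads, areas = p1_gradients(mesh)
    nv = mesh.n_vertices
    rows, cols, vals = [], [], []
    for i in range(3):
        for j in range(3):
            rows.append(mesh.triangles[:, i])
            cols.append(mesh.triangles[:, j])
            vals.append(areas * np.einsum("td,td->t", grads[:, i], grads[:, j]))
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nv, nv))
    return K.tocsr()


def _solve_dirichlet(K: sparse.csr_matrix, fixed: np.ndarray,
                     values: np.ndarray, rhs: np.ndarray | None = None
                     ) -> np.ndarray:
    nv = K.shape[0]
    free = ~fixed
    x = np.zeros(nv)
    x[fixed] = values[fixed]
    b = np.zeros(nv) if rhs is None else rhs.copy()
    b = b - K @ x
    Kff = K[free][:, free]
    x[free] = spsolve(Kff.tocsc(), b[free])
    return x


# ---------------------------------------------------------------------------
# boundary conditions

def detect_endcaps(mesh: CCMesh, corner_angle_deg: float = 45.0,
                   cap_search_mm: float = 10.0):
    """Locate free "end cap" boundary vertices around each endpoint.

    Returns (free_loop_positions, endpoint_clamp) where endpoint_clamp maps
    endpoint vertex index -> Dirichlet value or None (free).
    """
    if mesh.endpoints is None or mesh.chain_labels is None:
        raise LaplaceError("mesh endpoints/chains not set")
    loop = mesh.boundary
    pts = mesh.vertices[loop]
    nb = len(loop)
    threshold = np.deg2rad(corner_angle_deg)

    def walk(k0: int, step: int):
        """Walk the loop from position k0; return loop positions of the cap
        interior (strictly between endpoint and corner) or None if no
        corner found within the search distance."""
        freed = []
        arc = 0.0
        cum = 0.0
        prev_dir = None
        k = k0
        while arc < cap_search_mm:
            kn = (k + step) % nb
            d = pts[kn] - pts[k]
            seg = np.linalg.norm(d)
            if seg < 1e-12:
                k = kn
                continue
            ang = np.arctan2(d[1], d[0])
            if prev_dir is not None:
                turn = (ang - prev_dir + np.pi) % (2 * np.pi) - np.pi
                cum += turn
                if abs(cum) >= threshold:
                    return freed  # corner at position k; freed excludes it
            prev_dir = ang
            arc += seg
            if k != k0:
                freed.append(k)
            k = kn
        return None

    free_positions: set[int] = set()
    endpoint_clamp: dict[int, float | None] = {}
    loop_list = list(loop)
    for endpoint in mesh.endpoints:
        k0 = loop_list.index(endpoint)
        fwd = walk(k0, +1)
        bwd = walk(k0, -1)
        if fwd is not None and bwd is not None:
            free_positions.update(fwd)
            free_positions.update(bwd)
            endpoint_clamp[endpoint] = None
        elif fwd is None and bwd is None:
            endpoint_clamp[endpoint] = 0.0
        else:
            # cap on one side only: free it; clamp the endpoint with the
            # chain value of the cap-less side so straight ribbons with
            # corner endpoints stay exact
            capped = fwd if fwd is not None else bwd
            free_positions.update(capped)
            step = -1 if fwd is not None else +1
            edge_pos = k0 if step == +1 else (k0 - 1) % nb
            label = mesh.chain_labels[edge_pos]
            endpoint_clamp[endpoint] = -1.0 if label == INFERIOR else 1.0
    return free_positions, endpoint_clamp


def boundary_conditions(mesh: CCMesh, corner_angle_deg: float = 45.0,
                        cap_search_mm: float = 10.0):
    """Dirichlet mask and values for the primary potential."""
    nv = mesh.n_vertices
    fixed = np.zeros(nv, dtype=bool)
    values = np.zeros(nv)
    loop = mesh.boundary
    nb = len(loop)
    anterior, posterior = mesh.endpoints
    for k in range(nb):
        v0, v1 = int(loop[k]), int(loop[(k + 1) % nb])
        val = -1.0 if mesh.chain_labels[k] == INFERIOR else 1.0
        for v in (v0, v1):
            if v in (anterior, posterior):
                continue
            fixed[v] = True
            values[v] = val
    free_pos, endpoint_clamp = detect_endcaps(mesh, corner_angle_deg,
                                              cap_search_mm)
    for k in free_pos:
        v = int(loop[k])
        if v not in (anterior, posterior):
            fixed[v] = False
    for endpoint, val in endpoint_clamp.items():
        if val is None:
            fixed[endpoint] = False
        else:
            fixed[endpoint] = True
            values[endpoint] = val
    return fixed, values


def solve_laplace(mesh: CCMesh, corner_angle_deg: float = 45.0,
                  cap_search_mm: float = 10.0) -> np.ndarray:
    """Primary harmonic potential u with chain charges -1/+1."""
    K = stiffness_matrix(mesh)
    fixed, values = boundary_conditions(mesh, corner_angle_deg, cap_search_mm)
    if not fixed.any():
        raise LaplaceError("no Dirichlet vertices - chains unlabeled?")
    u = _solve_dirichlet(K, fixed, values)
    return u


def conjugate_potential(mesh: CCMesh, u: np.ndarray) -> np.ndarray:
    """Least-squares potential whose gradient matches the rotated gradient
    of u; gauge v=0 at the anterior endpoint, increasing toward posterior."""
    grads, areas = p1_gradients(mesh)
    gu = np.einsum("tid,ti->td", grads, u[mesh.triangles])
    w = np.column_stack([-gu[:, 1], gu[:, 0]])     # rotate +90 deg
    nv = mesh.n_vertices
    rhs = np.zeros(nv)
    for i in range(3):
        np.add.at(rhs, mesh.triangles[:, i],
                  areas * np.einsum("td,td->t", grads[:, i], w))
    K = stiffness_matrix(mesh)
    anterior, posterior = mesh.endpoints
    fixed = np.zeros(nv, dtype=bool)
    fixed[anterior] = True
    values = np.zeros(nv)
    v = _solve_dirichlet(K, fixed, values, rhs=rhs)
    if v[posterior] < v[anterior]:
        v = -v
    return v - v[anterior]


# ---------------------------------------------------------------------------
# level sets

def _perturb(field: np.ndarray, value: float) -> np.ndarray:
    d = field - value
    span = np.ptp(field)
    eps = max(span, 1.0) * 1e-12
    d[d == 0] = eps
    return d


def extract_level_set(mesh: CCMesh, field: np.ndarray, value: float):
    """Piecewise-linear level curve(s) of a per-vertex field.

    Returns a list of polylines, each a dict with keys ``points`` (m, 2)
    and ``edges`` (list of sorted vertex-index pairs, one per point).
    Level values outside the field range give an empty list.
    """
    if value < field.min() or value > field.max():
        return []
    d = _perturb(field, value)
    tris = mesh.triangles
    segments = []      # (key_a, key_b) per crossed triangle
    points: dict[tuple[int, int], np.ndarray] = {}
    sign = d > 0
    s = sign[tris]
    crossed = ~(s.all(axis=1) | (~s).all(axis=1))
    for t in np.where(crossed)[0]:
        keys = []
        for i in range(3):
            a, b = int(tris[t, i]), int(tris[t, (i + 1) % 3])
            if sign[a] != sign[b]:
                key = (min(a, b), max(a, b))
                if key not in points:
                    ta = d[a] / (d[a] - d[b])
                    points[key] = (mesh.vertices[a]
                                   + ta * (mesh.vertices[b] - mesh.vertices[a]))
                keys.append(key)
        if len(keys) == 2:
            segments.append((keys[0], keys[1]))

    adj: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for a, b in segments:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    polylines = []
    visited: set[tuple[int, int]] = set()
    starts = [k for k, nb in adj.items() if len(nb) == 1]
    starts += [k for k in adj if k not in starts]    # closed loops fallback
    for start in starts:
        if start in visited:
            continue
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = [k for k in adj[cur] if k not in visited]
            if not nxt:
                break
            cur = nxt[0]
            visited.add(cur)
            chain.append(cur)
        if len(chain) >= 2:
            polylines.append({
                "points": np.asarray([points[k] for k in chain]),
                "edges": chain,
            })
    return polylines


def _component_near(polylines, point):
    best, best_d = None, np.inf
    for pl in polylines:
        dmin = np.min(np.linalg.norm(pl["points"] - point, axis=1))
        if dmin < best_d:
            best, best_d = pl, dmin
    return best


def cap_edge_keys(mesh: CCMesh, corner_angle_deg: float = 45.0,
                  cap_search_mm: float = 10.0) -> set:
    """Boundary edges belonging to the free end caps (incl. endpoint)."""
    free_pos, endpoint_clamp = detect_endcaps(mesh, corner_angle_deg,
                                              cap_search_mm)
    loop = mesh.boundary
    nb = len(loop)
    free_verts = {int(loop[k]) for k in free_pos}
    free_verts.update(e for e, val in endpoint_clamp.items() if val is None)
    keys = set()
    for k in range(nb):
        a, b = int(loop[k]), int(loop[(k + 1) % nb])
        if a in free_verts or b in free_verts:
            keys.add((min(a, b), max(a, b)))
    return keys


def intercallosal_line(mesh: CCMesh, u: np.ndarray,
                       v: np.ndarray | None = None,
                       snap_tolerance_edges: float = 2.0) -> IntercallosalLine:
    """Zero level set of u, oriented anterior -> posterior.

    Line termini within ``snap_tolerance_edges`` local edge lengths of the
    endpoint vertices are snapped onto them.
    """
    polylines = extract_level_set(mesh, u, 0.0)
    if not polylines:
        raise LaplaceError("zero level set of u is empty")
    anterior, posterior = mesh.endpoints
    pa = mesh.vertices[anterior]
    pp = mesh.vertices[posterior]
    main = max(polylines, key=lambda pl: polyline_length(pl["points"]))
    pts = main["points"]
    edges = list(main["edges"])
    # orient anterior -> posterior
    if (np.linalg.norm(pts[0] - pa) + np.linalg.norm(pts[-1] - pp)
            > np.linalg.norm(pts[0] - pp) + np.linalg.norm(pts[-1] - pa)):
        pts = pts[::-1]
        edges = edges[::-1]

    vals_v = None
    if v is not None:
        vals_v = np.array([_edge_interp(mesh, u, v, key) for key in edges])

    # snap termini to the endpoint vertices when close enough
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    local = np.median(seg) if len(seg) else 1.0
    snapped = [False, False]
    if np.linalg.norm(pts[0] - pa) <= snap_tolerance_edges * local:
        if np.linalg.norm(pts[0] - pa) > 1e-12:
            pts = np.vstack([pa, pts])
            if vals_v is not None:
                vals_v = np.concatenate([[v[anterior]], vals_v])
        snapped[0] = True
    if np.linalg.norm(pts[-1] - pp) <= snap_tolerance_edges * local:
        if np.linalg.norm(pts[-1] - pp) > 1e-12:
            pts = np.vstack([pts, pp])
            if vals_v is not None:
                vals_v = np.concatenate([vals_v, [v[posterior]]])
        snapped[1] = True
    return IntercallosalLine(points=pts, values_v=vals_v,
                             snapped=tuple(snapped))


def _edge_interp(mesh, f_def, f_val, key):
    """Value of f_val at the point where f_def crosses zero on edge key."""
    a, b = key
    da, db = f_def[a], f_def[b]
    if da == db:
        t = 0.5
    else:
        t = da / (da - db)
    t = np.clip(t, 0.0, 1.0)
    return (1 - t) * f_val[a] + t * f_val[b]


def line_length(line: IntercallosalLine) -> float:
    return line.length


def line_curvature(line: IntercallosalLine, resample_step: float = 2.0
                   ) -> float:
    """Mean unsigned curvature: total |turning angle| / covered arc length.

    The polyline is resampled at ``resample_step`` mm first to suppress
    discretization jitter; the denominator excludes the half-segments
    beyond the first/last turning vertices so circles are unbiased.
    """
    pts = resample_polyline(line.points, resample_step)
    if len(pts) < 3:
        return 0.0
    ang = turning_angles(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    covered = seg.sum() - 0.5 * (seg[0] + seg[-1])
    if covered <= 0:
        return 0.0
    return float(np.sum(np.abs(ang)) / covered)


def thickness_profile(mesh: CCMesh, u: np.ndarray, v: np.ndarray,
                      line: IntercallosalLine, n: int = 100
                      ) -> ThicknessProfile:
    """Thickness t_i at n equally arc-length-spaced samples of the line.

    Each sample takes the conjugate-potential value at the sample point and
    measures the length of that v-level path (the connected component
    through the sample) between the inferior and superior chains.  Samples
    whose level path does not join oppositely labeled chains are flagged
    NaN rather than failing globally.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if line.values_v is None:
        raise LaplaceError("line carries no conjugate-potential values")
    edge_labels = mesh.boundary_edge_labels()
    caps = cap_edge_keys(mesh)
    total = line.length
    al = line.arc_length
    positions = (np.arange(n) + 0.5) / n
    thickness = np.full(n, np.nan)
    paths: list = [None] * n

    def is_valid(comp):
        if comp is None or len(comp["points"]) < 2:
            return False
        e0, e1 = comp["edges"][0], comp["edges"][-1]
        if e0 in caps or e1 in caps:
            return False
        l0, l1 = edge_labels.get(e0), edge_labels.get(e1)
        return l0 is not None and l1 is not None and l0 != l1

    for i, s in enumerate(positions):
        target = s * total
        p = point_at_arclength(line.points, target)
        v_i = float(np.interp(target, al, line.values_v))
        comps = extract_level_set(mesh, v, v_i)
        valid_comps = [c for c in comps if is_valid(c)]
        comp = _component_near(valid_comps, p)
        if comp is None:
            comp = _component_near(comps, p)
            if comp is not None:
                paths[i] = comp["points"]     # flagged missing, kept for QC
            continue
        thickness[i] = polyline_length(comp["points"])
        paths[i] = comp["points"]
    return ThicknessProfile(positions=positions, thickness=thickness,
                            level_paths=paths)


# ---------------------------------------------------------------------------
# gradient-streamline oracle (validation of the level-path shortcut)

class _Locator:
    def __init__(self, mesh: CCMesh):
        self.mesh = mesh
        self.centroids = mesh.vertices[mesh.triangles].mean(axis=1)
        self.tree = cKDTree(self.centroids)

    def find(self, point, k: int = 24):
        _, idx = self.tree.query(point, k=min(k, len(self.centroids)))
        idx = np.atleast_1d(idx)
        for t in idx:
            if self._bary_inside(int(t), point, 1e-9):
                return int(t)
        for t in range(len(self.mesh.triangles)):
            if self._bary_inside(t, point, 1e-9):
                return t
        return None

    def _bary_inside(self, t, point, tol):
        tri = self.mesh.triangles[t]
        p = self.mesh.vertices[tri]
        m = np.column_stack([p[1] - p[0], p[2] - p[0]])
        try:
            lam = np.linalg.solve(m, np.asarray(point) - p[0])
        except np.linalg.LinAlgError:
            return False
        l0 = 1 - lam.sum()
        return (lam >= -tol).all() and l0 >= -tol


def _trace(mesh: CCMesh, grads_u: np.ndarray, locator: _Locator,
           start, direction: int, edge_labels, target_label,
           max_steps: int = 20000):
    """Follow the per-triangle gradient until the target chain is reached.

    Returns path length or None on failure.
    """
    tri_adj = _triangle_adjacency(mesh)
    t = locator.find(start)
    if t is None:
        return None
    x = np.asarray(start, dtype=float)
    length = 0.0
    eps = 1e-10
    jitters = 0
    for _ in range(max_steps):
        g = grads_u[t] * direction
        ng = np.linalg.norm(g)
        if ng < 1e-14:
            return None
        g = g / ng
        tri = mesh.triangles[t]
        p = mesh.vertices[tri]
        best_s, best_e = np.inf, None
        for i in range(3):
            a, b = p[i], p[(i + 1) % 3]
            e = b - a
            denom = g[0] * (-e[1]) + g[1] * e[0]
            if abs(denom) < 1e-14:
                continue
            # solve x + s*g = a + r*e
            rhs = a - x
            s_val = (rhs[0] * (-e[1]) + rhs[1] * e[0]) / denom
            r_val = (g[0] * rhs[1] - g[1] * rhs[0]) / denom
            if s_val > eps and -1e-9 <= r_val <= 1 + 1e-9:
                if s_val < best_s:
                    best_s = s_val
                    best_e = (int(tri[i]), int(tri[(i + 1) % 3]))
        if best_e is None:
            # stalled, usually by hitting a vertex exactly: terminate if we
            # already sit on a boundary edge, otherwise jitter sideways
            for i in range(3):
                a, b = int(tri[i]), int(tri[(i + 1) % 3])
                key = (min(a, b), max(a, b))
                if tri_adj.get((t, key)) is not None:
                    continue
                pa, pb = mesh.vertices[a], mesh.vertices[b]
                e = pb - pa
                tt = np.clip((x - pa) @ e / (e @ e), 0, 1)
                if np.linalg.norm(x - (pa + tt * e)) < 1e-6:
                    if edge_labels.get(key) == target_label:
                        return length
                    return None
            if jitters >= 4:
                return None
            jitters += 1
            perp = np.array([-g[1], g[0]])
            x = x + (1e-7 * (-1) ** jitters * jitters) * perp + 1e-9 * g
            tn = locator.find(x)
            if tn is None:
                return None
            t = tn
            continue
        x_new = x + best_s * g
        length += best_s
        key = (min(best_e), max(best_e))
        nxt = tri_adj.get((t, key))
        if nxt is None:
            # boundary edge
            if edge_labels.get(key) == target_label:
                return length
            return None
        x = x_new + 1e-9 * g
        t = nxt
    return None


_ADJ_CACHE: dict[int, dict] = {}


def _triangle_adjacency(mesh: CCMesh):
    cache_key = id(mesh)
    if cache_key in _ADJ_CACHE:
        return _ADJ_CACHE[cache_key]
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for t, tri in enumerate(mesh.triangles):
        for i in range(3):
            a, b = int(tri[i]), int(tri[(i + 1) % 3])
            edge_tris.setdefault((min(a, b), max(a, b)), []).append(t)
    adj = {}
    for key, ts in edge_tris.items():
        if len(ts) == 2:
            adj[(ts[0], key)] = ts[1]
            adj[(ts[1], key)] = ts[0]
        else:
            adj[(ts[0], key)] = None
    _ADJ_CACHE.clear()        # keep a single mesh cached
    _ADJ_CACHE[cache_key] = adj
    return adj


def streamline_thickness(mesh: CCMesh, u: np.ndarray,
                         line: IntercallosalLine, n: int = 100) -> np.ndarray:
    """Thickness by explicit gradient-curve tracing (independent oracle).

    From each sample point on the intercallosal line, integrate the u
    gradient forward to the superior chain and backward to the inferior
    chain; thickness is the combined path length.  NaN on tracing failure.
    """
    grads, _ = p1_gradients(mesh)
    gu = np.einsum("tid,ti->td", grads, u[mesh.triangles])
    locator = _Locator(mesh)
    edge_labels = mesh.boundary_edge_labels()
    total = line.length
    out = np.full(n, np.nan)
    for i in range(n):
        s = (i + 0.5) / n
        p = point_at_arclength(line.points, s * total)
        up = _trace(mesh, gu, locator, p, +1, edge_labels, SUPERIOR)
        down = _trace(mesh, gu, locator, p, -1, edge_labels, INFERIOR)
        if up is not None and down is not None:
            out[i] = up + down
    return out
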