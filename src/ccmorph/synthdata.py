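"""Synthetic CC-like fixtures with analytic ground truth.

Everything every pipeline stage needs can be generated here without any
download: bent-ribbon masks with known centerline/thickness/curvature,
analytic polygon contours for the same shapes (bypassing rasterization),
paired label volumes related by a known rigid transform, and test-retest
mask pairs with pose jitter and boundary noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import ndimage

from .geometry import rigid_2d, apply_2d
from .midplane import LabelMap, RigidTransform


class SynthError(RuntimeError):
    pass


def _thickness_fn(kind: str, params: tuple):
    if kind == "constant":
        h, = params
        return lambda s: np.full_like(np.asarray(s, dtype=float), h)
    if kind == "linear":
        h0, h1 = params
        return lambda s: h0 + (h1 - h0) * np.asarray(s, dtype=float)
    if kind == "smooth":
        h0, h1 = params
        return lambda s: h0 + (h1 - h0) * np.asarray(s, dtype=float) ** 2
    raise SynthError(f"unknown thickness profile '{kind}'")


@dataclass
class RibbonSpec:
    """Parametric ribbon: circular-arc or straight centerline plus a
    half-width function of normalized arc position s in [0, 1]."""

    kind: str = "arc"                       # "arc" | "straight"
    radius: float = 12.5                    # arc: centerline radius (mm)
    span: float = np.pi                     # arc: angular span (rad)
    length: float = 20.0                    # straight: centerline length
    thickness: str = "constant"             # half-width profile family
    thickness_params: tuple = (2.5,)
    resolution: float = 0.5                 # mm per pixel
    landmark_offset: tuple = (0.0, -5.0)    # AC/PC offset from the ends
    pose: np.ndarray | None = None          # optional 3x3 rigid transform

    def half_width(self, s):
        return _thickness_fn(self.thickness, self.thickness_params)(s)

    def centerline_length(self) -> float:
        return self.radius * self.span if self.kind == "arc" else self.length

    def centerline_curvature(self) -> float:
        return 1.0 / self.radius if self.kind == "arc" else 0.0

    def centerline_point(self, s):
        """Centerline point(s); s=0 is the anterior end (+a side)."""
        s = np.asarray(s, dtype=float)
        if self.kind == "arc":
            th = self.span * s
            return np.stack([self.radius * np.cos(th),
                             self.radius * np.sin(th)], axis=-1)
        return np.stack([self.length * (1.0 - s), np.zeros_like(s)], axis=-1)


@dataclass
class GroundTruth:
    length_mm: float
    curvature_per_mm: float
    area_mm2: float
    thickness_positions: np.ndarray
    thickness_samples: np.ndarray
    ac: np.ndarray
    pc: np.ndarray


def _ribbon_geometry(spec: RibbonSpec):
    """Return (inside_fn, ac, pc, bounds) in the canonical (unposed) frame.

    Arc ribbons open upward with the anterior end at angle 0 (so anterior
    is +a); straight ribbons run along the a axis with the anterior end at
    a = length.
    """
    hw = _thickness_fn(spec.thickness, spec.thickness_params)
    if spec.kind == "arc":
        r0, span = spec.radius, spec.span

        def inside(p):
            r = np.linalg.norm(p, axis=-1)
            th = np.arctan2(p[..., 1], p[..., 0])
            s = th / span
            ok = (th >= 0) & (s <= 1.0)
            return ok & (np.abs(r - r0) <= hw(np.clip(s, 0, 1)))

        end_a = np.array([r0, 0.0])
        end_p = np.array([r0 * np.cos(span), r0 * np.sin(span)])
        hmax = float(np.max(hw(np.linspace(0, 1, 201))))
        bounds = (-(r0 + hmax) - 1, (r0 + hmax) + 1,
                  min(0.0, end_p[1]) - 1, (r0 + hmax) + 1)
    elif spec.kind == "straight":
        L = spec.length

        def inside(p):
            t = 1.0 - p[..., 0] / L
            ok = (t >= 0) & (t <= 1)
            return ok & (np.abs(p[..., 1]) <= hw(np.clip(t, 0, 1)))

        end_a = np.array([L, 0.0])
        end_p = np.array([0.0, 0.0])
        hmax = float(np.max(hw(np.linspace(0, 1, 201))))
        bounds = (-1.0, L + 1.0, -hmax - 1, hmax + 1)
    else:
        raise SynthError(f"unknown ribbon kind '{spec.kind}'")

    off = np.asarray(spec.landmark_offset, dtype=float)
    ac = end_a + off
    pc = end_p + off
    return inside, ac, pc, bounds


def ribbon_ground_truth(spec: RibbonSpec, n_samples: int = 100) -> GroundTruth:
    """Closed-form geometry of the ribbon (in the canonical frame)."""
    _, ac, pc, _ = _ribbon_geometry(spec)
    s = (np.arange(n_samples) + 0.5) / n_samples
    hw = spec.half_width(s)
    L = spec.centerline_length()
    # area: arc bands have dA = 2 r0 hw dtheta exactly; straight analogous
    s_fine = np.linspace(0, 1, 4001)
    area = float(np.trapezoid(2 * spec.half_width(s_fine), s_fine) * L)
    return GroundTruth(
        length_mm=L,
        curvature_per_mm=spec.centerline_curvature(),
        area_mm2=area,
        thickness_positions=s,
        thickness_samples=2 * hw,
        ac=ac, pc=pc,
    )


def generate_ribbon(spec: RibbonSpec, seed: int = 0,
                    noise_flip_prob: float = 0.0):
    """Rasterize the ribbon onto a pixel grid.

    Returns (mask, origin, landmarks, GroundTruth); world coordinates of
    ``mask[i, j]`` are ``origin + (i, j) * resolution``.  Deterministic for
    a fixed seed.
    """
    inside, ac, pc, bounds = _ribbon_geometry(spec)
    pose = spec.pose
    res = spec.resolution
    x0, x1, y0, y1 = bounds
    if pose is not None:
        corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        moved = apply_2d(pose, corners)
        x0, y0 = moved.min(axis=0) - 1
        x1, y1 = moved.max(axis=0) + 1
        inv = np.linalg.inv(pose)
        ac = apply_2d(pose, ac[None])[0]
        pc = apply_2d(pose, pc[None])[0]
    # half-pixel offset keeps pixel centers off exact shape boundaries
    # (unbiased pixel-count area for axis-aligned rectangles)
    origin = np.array([x0 + res / 2, y0 + res / 2])
    ni = int(np.ceil((x1 - x0) / res)) + 1
    nj = int(np.ceil((y1 - y0) / res)) + 1
    ii, jj = np.meshgrid(np.arange(ni), np.arange(nj), indexing="ij")
    pts = origin + np.stack([ii, jj], axis=-1) * res
    if pose is not None:
        pts = pts @ inv[:2, :2].T + inv[:2, 2]
    mask = inside(pts)
    if not mask.any():
        raise SynthError("ribbon rasterized to an empty mask")
    if noise_flip_prob > 0:
        rng = np.random.default_rng(seed)
        er = ndimage.binary_erosion(mask)
        di = ndimage.binary_dilation(mask)
        band = di & ~er                      # boundary band, inside + outside
        flips = band & (rng.random(mask.shape) < noise_flip_prob)
        mask = mask ^ flips
        mask = ndimage.binary_closing(mask)  # keep the component simple
    truth = ribbon_ground_truth(spec)
    landmarks = {"AC": ac.tolist(), "PC": pc.tolist()}
    return mask.astype(np.uint8), origin, landmarks, truth


def ribbon_contour(spec: RibbonSpec, points_per_mm: float = 4.0):
    """Analytic polygon outline of the ribbon (no rasterization).

    Returns (vertices CCW, landmarks dict).  Useful for convergence and
    exactness tests where rasterization error would dominate.
    """
    _, ac, pc, _ = _ribbon_geometry(spec)
    n = max(int(spec.centerline_length() * points_per_mm), 8)
    s = np.linspace(0.0, 1.0, n + 1)
    hw = spec.half_width(s)
    if spec.kind == "arc":
        th = spec.span * s
        outer_r = spec.radius + hw
        inner_r = spec.radius - hw
        outer = np.column_stack([outer_r * np.cos(th), outer_r * np.sin(th)])
        inner = np.column_stack([inner_r * np.cos(th), inner_r * np.sin(th)])
        verts = np.vstack([outer, inner[::-1]])
    else:
        a = spec.length * (1.0 - s)
        top = np.column_stack([a, hw])
        bot = np.column_stack([a, -hw])
        verts = np.vstack([top, bot[::-1]])
    landmarks = {"AC": ac.tolist(), "PC": pc.tolist()}
    return verts, landmarks


# ---------------------------------------------------------------------------
# label volumes for registration fixtures

def generate_label_volume(n_labels: int = 8,
                          transform: RigidTransform | None = None,
                          seed: int = 0, shape=(80, 80, 80),
                          blob_radius: float = 6.0):
    """Template label volume + the same volume resampled under a rigid
    transform, with the ground-truth transform returned.

    The recovered registration maps the transformed (subject) volume back
    onto the template.
    """
    if n_labels < 4:
        raise SynthError("need at least 4 labels for a non-degenerate cloud")
    rng = np.random.default_rng(seed)
    shape = tuple(shape)
    margin = blob_radius + 8
    centers = rng.uniform(margin, np.asarray(shape) - margin,
                          size=(n_labels, 3))
    # reject near-coplanar configurations by re-drawing
    for _ in range(50):
        c = centers - centers.mean(axis=0)
        if np.linalg.svd(c, compute_uv=False)[-1] > 2.0:
            break
        centers = rng.uniform(margin, np.asarray(shape) - margin,
                              size=(n_labels, 3))
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape],
                                indexing="ij"), axis=-1).astype(float)
    template = np.zeros(shape, dtype=np.int16)
    for lab, c in enumerate(centers, start=1):
        d = np.linalg.norm(grid - c, axis=-1)
        template[d <= blob_radius] = lab
    if transform is None:
        transform = RigidTransform.identity()
    # subject[x] = template[T(x)] so T maps subject -> template space
    subject = ndimage.affine_transform(
        template, transform.rotation, offset=transform.translation,
        order=0, mode="constant", cval=0)
    affine = np.eye(4)
    tpl_map = LabelMap(voxels=template, affine=affine)
    subj_map = LabelMap(voxels=subject, affine=affine)
    missing = set(range(1, n_labels + 1)) - set(np.unique(subject).tolist())
    if missing:
        raise SynthError(f"labels pushed outside the field of view: "
                         f"{sorted(missing)}")
    return tpl_map, subj_map, transform


# ---------------------------------------------------------------------------
# test-retest cohorts

@dataclass
class RetestSubject:
    scans: list                       # two (mask, origin, landmarks) tuples
    covariates: dict = dataclass_field(default_factory=dict)
    true_mean_thickness: float = 0.0


def generate_test_retest(n_subjects: int = 20, pose_jitter_deg: float = 2.0,
                         noise_flip_prob: float = 0.0, seed: int = 0,
                         resolution: float = 0.5,
                         group_effect_mm: float = 0.0):
    """Paired rasterizations of per-subject ribbons under small pose
    perturbations, plus covariates and an optional group thickness effect.

    Subjects alternate group 0/1; group 1 ("patients") lose
    ``group_effect_mm`` of thickness uniformly.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n_subjects):
        group = i % 2
        age = float(rng.uniform(40, 75))
        sex = int(rng.integers(0, 2))
        tbv = float(rng.normal(1.35e6, 1e5))
        base = 2.5 + 0.4 * rng.standard_normal() - 0.5 * group_effect_mm * group
        base = max(base, 1.2)
        scans = []
        for scan in range(2):
            ang = np.deg2rad(rng.uniform(-pose_jitter_deg, pose_jitter_deg))
            # translation jitter scales with the pose jitter (zero -> zero)
            shift = rng.uniform(-1.0, 1.0, size=2) * 0.25 * pose_jitter_deg
            spec = RibbonSpec(kind="arc", radius=12.5, span=np.pi,
                              thickness="linear",
                              thickness_params=(base, base + 0.8),
                              resolution=resolution,
                              pose=rigid_2d(ang, shift))
            mask, origin, landmarks, _ = generate_ribbon(
                spec, seed=int(rng.integers(0, 2 ** 31)),
                noise_flip_prob=noise_flip_prob)
            scans.append((mask, origin, landmarks))
        truth = ribbon_ground_truth(
            RibbonSpec(kind="arc", radius=12.5, span=np.pi,
                       thickness="linear", thickness_params=(base, base + 0.8),
                       resolution=resolution))
        subjects.append(RetestSubject(
            scans=scans,
            covariates={"group": group, "age": age, "sex": sex, "tbv": tbv},
            true_mean_thickness=float(truth.thickness_samples.mean())))
    return subjects
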