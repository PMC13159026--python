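"""Mid-sagittal plane estimation and slice handling.

The subject plane is found by rigidly registering label centroids of the
subject segmentation onto a template segmentation (Kabsch/SVD) and pulling
the template's mid-plane back through the inverse transform.  World
coordinates are RAS mm throughout; voxel centers sit at integer indices
and the NIfTI affine is applied homogeneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class MidplaneError(RuntimeError):
    pass


@dataclass
class LabelMap:
    """3D integer label volume with voxel-index -> world-RAS affine."""

    voxels: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise MidplaneError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MidplaneError("affine is singular")

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def labels(self) -> np.ndarray:
        lab = np.unique(self.voxels)
        return lab[lab != 0]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass
class CentroidCloud:
    labels: np.ndarray
    points: np.ndarray          # (n, 3) world mm


@dataclass
class RigidTransform:
    """4x4 homogeneous proper rigid transform."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        R = self.matrix[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise MidplaneError("rotation part is not orthonormal")
        if np.linalg.det(R) < 0:
            raise MidplaneError("transform contains a reflection")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        inv = np.eye(4)
        inv[:3, :3] = self.rotation.T
        inv[:3, 3] = -self.rotation.T @ self.translation
        return RigidTransform(inv)

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other (matrix product self @ other)."""
        return RigidTransform(self.matrix @ other.matrix)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotvec_translation(cls, rotvec, translation) -> "RigidTransform":
        from scipy.spatial.transform import Rotation
        m = np.eye(4)
        m[:3, :3] = Rotation.from_rotvec(rotvec).as_matrix()
        m[:3, 3] = translation
        return cls(m)


@dataclass
class Plane:
    """Oriented plane with an in-plane right-handed frame.

    ``axes[0]`` points anterior, ``axes[1]`` superior; together with
    ``normal`` (left-right) they form a right-handed orthonormal triple.
    """

    point: np.ndarray
    normal: np.ndarray
    axes: np.ndarray            # (2, 3)

    def __post_init__(self):
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        self.normal = n / np.linalg.norm(n)
        self.axes = np.asarray(self.axes, dtype=float)

    def frame_matrix(self) -> np.ndarray:
        """4x4 transform: plane coordinates (a, s, offset) -> world."""
        m = np.eye(4)
        m[:3, 0] = self.axes[0]
        m[:3, 1] = self.axes[1]
        m[:3, 2] = self.normal
        m[:3, 3] = self.point
        return m

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal

    @classmethod
    def from_frame_matrix(cls, m: np.ndarray) -> "Plane":
        m = np.asarray(m, dtype=float)
        return cls(point=m[:3, 3], normal=m[:3, 2], axes=m[:3, :2].T)


@dataclass
class SliceStack:
    slices: np.ndarray          # (n_slices, na, ns)
    in_plane_resolution: float
    slice_spacing: float
    offsets: np.ndarray         # signed mm from mid-plane
    origin: tuple[float, float] = (0.0, 0.0)   # (a, s) of slice pixel [0, 0]

    @property
    def mid_slice(self) -> np.ndarray:
        return self.slices[len(self.slices) // 2]


# ---------------------------------------------------------------------------

def compute_label_centroids(label_map: LabelMap, labels=None,
                            exclude=()) -> CentroidCloud:
    """Per-label centroid of voxel-center world coordinates."""
    if labels is None:
        labels = label_map.labels()
    labels = np.asarray([l for l in labels if l not in set(exclude)])
    if len(labels) == 0:
        raise MidplaneError("no labels requested")
    present = set(np.unique(label_map.voxels).tolist())
    missing = [int(l) for l in labels if int(l) not in present]
    if missing:
        raise MidplaneError(f"labels missing from volume: {missing}")
    idx_centroids = ndimage.center_of_mass(
        np.ones_like(label_map.voxels, dtype=np.uint8), label_map.voxels,
        labels)
    points = label_map.index_to_world(np.asarray(idx_centroids))
    return CentroidCloud(labels=labels, points=points)


def rigid_register_centroids(source: CentroidCloud,
                             target: CentroidCloud) -> RigidTransform:
    """Least-squares rigid transform mapping source points onto target.

    Kabsch algorithm on label-matched centroids; a reflection in the SVD
    solution is corrected by flipping the weakest singular direction.
    """
    shared = sorted(set(source.labels.tolist()) & set(target.labels.tolist()))
    if len(shared) < 3:
        raise MidplaneError(
            f"need >=3 shared labels, got {len(shared)}")
    src = np.array([source.points[list(source.labels).index(l)]
                    for l in shared])
    tgt = np.array([target.points[list(target.labels).index(l)]
                    for l in shared])
    sc, tc = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - sc).T @ (tgt - tc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1e-300):
        raise MidplaneError("centroid configuration is rank deficient "
                            "(collinear labels)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ sc
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = t
    return RigidTransform(m)


def map_template_midplane(T: RigidTransform, template_plane: Plane) -> Plane:
    """Pull the template mid-plane back to subject space via T^-1."""
    inv = T.inverse()
    point = inv.apply(template_plane.point)
    normal = inv.rotation @ template_plane.normal
    axes = (inv.rotation @ template_plane.axes.T).T
    return Plane(point=point, normal=normal, axes=axes)


def template_midplane_from_labelmap(template: LabelMap) -> Plane:
    """Mid-plane through the template volume's left-right center.

    Normal along the world L-R (first RAS) axis; in-plane axes anterior
    and superior.
    """
    shape = np.asarray(template.voxels.shape, dtype=float)
    center = template.index_to_world((shape - 1) / 2)
    return Plane(point=center, normal=(1.0, 0.0, 0.0),
                 axes=np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]))


def slice_count(half_width_mm: float, spacing: float) -> int:
    """Smallest odd slice count whose outer slice spans half_width_mm.

    Slices sit at offsets k*spacing; each covers spacing/2 to either side.
    """
    if spacing <= 0:
        raise MidplaneError("spacing must be positive")
    k = int(np.ceil(max(half_width_mm - spacing / 2, 0.0) / spacing - 1e-12))
    return 2 * k + 1


def extract_midsagittal_slices(volume: np.ndarray, affine: np.ndarray,
                               plane: Plane, half_width_mm: float = 2.5,
                               spacing: float | None = None,
                               in_plane_resolution: float | None = None,
                               is_mask: bool = False) -> SliceStack:
    """Resample slices parallel to the plane from a 3D volume.

    Linear interpolation for intensities, nearest neighbor for masks;
    samples outside the volume fill with 0.
    """
    volume = np.asarray(volume)
    affine = np.asarray(affine, dtype=float)
    vox = np.linalg.norm(affine[:3, :3], axis=0)
    if spacing is None:
        spacing = float(min(vox))
    if in_plane_resolution is None:
        in_plane_resolution = float(min(vox))
    n_slices = slice_count(half_width_mm, spacing)
    k = n_slices // 2
    offsets = np.arange(-k, k + 1) * spacing

    # in-plane extent: project the volume's corner points onto the axes
    corners_idx = np.array([[i, j, l] for i in (0, volume.shape[0] - 1)
                            for j in (0, volume.shape[1] - 1)
                            for l in (0, volume.shape[2] - 1)], dtype=float)
    corners = corners_idx @ affine[:3, :3].T + affine[:3, 3]
    rel = corners - plane.point
    a_rng = rel @ plane.axes[0]
    s_rng = rel @ plane.axes[1]
    d_rng = rel @ plane.normal
    if d_rng.min() > 0 or d_rng.max() < 0:
        raise MidplaneError("plane lies entirely outside the volume")
    a = np.arange(a_rng.min(), a_rng.max() + 1e-9, in_plane_resolution)
    s = np.arange(s_rng.min(), s_rng.max() + 1e-9, in_plane_resolution)

    inv = np.linalg.inv(affine)
    slices = np.empty((n_slices, len(a), len(s)), dtype=float)
    A, S = np.meshgrid(a, s, indexing="ij")
    for si, off in enumerate(offsets):
        world = (plane.point
                 + A[..., None] * plane.axes[0]
                 + S[..., None] * plane.axes[1]
                 + off * plane.normal)
        idx = world @ inv[:3, :3].T + inv[:3, 3]
        coords = np.moveaxis(idx, -1, 0)
        order = 0 if is_mask else 1
        slices[si] = ndimage.map_coordinates(volume.astype(float), coords,
                                             order=order, mode="constant",
                                             cval=0.0)
    return SliceStack(slices=slices, in_plane_resolution=in_plane_resolution,
                      slice_spacing=spacing, offsets=offsets,
                      origin=(float(a[0]), float(s[0])))


def plane_disagreement(a: Plane, b: Plane, radius_mm: float,
                       n_radial: int = 200, n_angular: int = 256) -> float:
    """Volume (mm^3) between two planes inside an origin-centered cylinder.

    The cylinder axis runs through the RAS origin along the planes' mean
    unit normal; the integrand |height_a - height_b| is integrated on a
    polar midpoint grid that is exact for constant integrands.
    """
    na = a.normal / np.linalg.norm(a.normal)
    nb = b.normal / np.linalg.norm(b.normal)
    if na @ nb < 0:
        nb = -nb
    axis = na + nb
    axis = axis / np.linalg.norm(axis)
    # orthonormal in-disk frame
    e1 = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(e1) < 1e-8:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    # midpoint grid uniform in r^2 and theta: equal-area cells
    r2_edges = np.linspace(0.0, radius_mm ** 2, n_radial + 1)
    r = np.sqrt(0.5 * (r2_edges[:-1] + r2_edges[1:]))
    theta = (np.arange(n_angular) + 0.5) * (2 * np.pi / n_angular)
    R, TH = np.meshgrid(r, theta, indexing="ij")
    pts = (R * np.cos(TH))[..., None] * e1 + (R * np.sin(TH))[..., None] * e2

    def height(plane, n_aligned):
        denom = n_aligned @ axis
        if abs(denom) < 1e-9:
            raise MidplaneError("plane normal perpendicular to cylinder axis")
        return ((plane.point - pts) @ n_aligned) / denom

    dz = np.abs(height(a, na) - height(b, nb))
    cell_area = np.pi * radius_mm ** 2 / (n_radial * n_angular)
    return float(dz.sum() * cell_area)


def standardize_head_pose(ac, pc, midplane: Plane) -> RigidTransform:
    """Transform placing AC at the origin, PC on the -anterior axis, and
    the mid-plane normal along the left-right axis.

    The frame is Gram-Schmidt orthogonalized in the order {normal,
    AC-PC direction projected into the plane, cross product}.
    """
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    if np.allclose(ac, pc):
        raise MidplaneError("AC and PC coincide")
    e_lr = midplane.normal / np.linalg.norm(midplane.normal)
    ap = ac - pc
    ap_in_plane = ap - (ap @ e_lr) * e_lr
    norm = np.linalg.norm(ap_in_plane)
    if norm < 1e-9:
        raise MidplaneError("AC-PC direction parallel to mid-plane normal")
    e_a = ap_in_plane / norm
    e_s = np.cross(e_lr, e_a)
    R = np.vstack([e_lr, e_a, e_s])        # rows: new LR, AP, SI axes
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = -R @ ac
    return RigidTransform(m)
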