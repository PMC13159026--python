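"""Summary shape metrics of the mid-sagittal CC."""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .laplace import IntercallosalLine, ThicknessProfile
from .meshing import CCMesh


class MetricsError(RuntimeError):
    pass


@dataclass
class ShapeMetrics:
    area_mm2: float
    perimeter_mm: float
    circularity: float
    cc_index: float
    length_mm: float
    curvature_per_mm: float
    mean_thickness_mm: float
    volume5_mm3: float

    def as_dict(self) -> dict:
        return asdict(self)


def area_perimeter(mesh: CCMesh) -> tuple[float, float]:
    return mesh.area(), mesh.perimeter()


def circularity(area: float, perimeter: float) -> float:
    """4*pi*area / perimeter^2 — 1 for a disk, less for elongated shapes."""
    if perimeter <= 0:
        raise MetricsError("perimeter must be positive")
    return 4 * np.pi * area / perimeter ** 2


def ap_extent(mesh: CCMesh) -> float:
    """Anterior-posterior extent of the boundary (projection onto a)."""
    a = mesh.boundary_points[:, 0]
    return float(a.max() - a.min())


def cc_index(profile: ThicknessProfile, line: IntercallosalLine,
             mesh: CCMesh, fractions=(0.1, 0.5, 0.9)) -> float:
    """Summed thickness at three arc positions over the AP extent."""
    extent = ap_extent(mesh)
    if extent <= 0:
        raise MetricsError("degenerate AP extent")
    valid = profile.valid
    if valid.sum() < 2:
        raise MetricsError("too few valid thickness samples")
    pos = profile.positions[valid]
    thick = profile.thickness[valid]
    total = 0.0
    for f in fractions:
        if f < pos[0] - 0.05 or f > pos[-1] + 0.05:
            raise MetricsError(f"no thickness available near fraction {f}")
        total += float(np.interp(f, pos, thick))
    return total / extent


def mean_thickness(profile: ThicknessProfile) -> float:
    valid = profile.valid
    if not valid.any():
        raise MetricsError("all thickness samples missing")
    return float(np.mean(profile.thickness[valid]))


def volume_5mm(slice_areas, spacing: float, offsets=None,
               half_width: float = 2.5) -> float:
    """Resolution-corrected volume over a fixed-width slab.

    Each slice contributes its area times the overlap of its thickness
    interval [x - spacing/2, x + spacing/2] with [-half_width, half_width],
    so the estimate reflects a consistent 2*half_width mm slab regardless
    of voxel size.
    """
    slice_areas = np.asarray(slice_areas, dtype=float)
    n = len(slice_areas)
    if offsets is None:
        k = n // 2
        offsets = (np.arange(n) - k) * spacing
    offsets = np.asarray(offsets, dtype=float)
    lo = offsets - spacing / 2
    hi = offsets + spacing / 2
    if lo.min() > -half_width + 1e-9 or hi.max() < half_width - 1e-9:
        raise MetricsError(
            f"slice stack covers [{lo.min():.2f}, {hi.max():.2f}] mm, "
            f"needs [-{half_width}, {half_width}]")
    overlap = np.clip(np.minimum(hi, half_width)
                      - np.maximum(lo, -half_width), 0.0, None)
    return float(np.sum(slice_areas * overlap))


def slice_areas_from_stack(slices: np.ndarray, in_plane_resolution: float
                           ) -> np.ndarray:
    """Pixel-count areas (mm^2) of binary slices."""
    s = np.asarray(slices)
    return s.reshape(len(s), -1).sum(axis=1) * in_plane_resolution ** 2


def compute_shape_metrics(mesh: CCMesh, profile: ThicknessProfile,
                          line: IntercallosalLine, curvature: float,
                          slice_areas=None, spacing: float | None = None,
                          half_width: float = 2.5,
                          cc_index_fractions=(0.1, 0.5, 0.9)) -> ShapeMetrics:
    area, perim = area_perimeter(mesh)
    if slice_areas is not None and spacing is not None:
        vol5 = volume_5mm(slice_areas, spacing, half_width=half_width)
    else:
        vol5 = area * 2 * half_width       # single-slice fallback
    return ShapeMetrics(
        area_mm2=area,
        perimeter_mm=perim,
        circularity=circularity(area, perim),
        cc_index=cc_index(profile, line, mesh, cc_index_fractions),
        length_mm=line.length,
        curvature_per_mm=curvature,
        mean_thickness_mm=mean_thickness(profile),
        volume5_mm3=vol5,
    )
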