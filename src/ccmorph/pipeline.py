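"""End-to-end orchestration: mask (+ landmarks) -> mesh -> Laplace fields ->
thickness profile -> shape metrics -> sub-segmentation, with a run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as ccio
from .laplace import (conjugate_potential, intercallosal_line, line_curvature,
                      solve_laplace, thickness_profile)
from .meshing import CCMesh, build_cc_mesh
from .morphometrics import compute_shape_metrics, slice_areas_from_stack
from .subseg import subsegment

logger = logging.getLogger("ccmorph")
if not logger.handlers:
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("[ccmorph] %(message)s"))
    logger.addHandler(_handler)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    mask_path: str | None = None
    landmarks_path: str | None = None
    mesh_path: str | None = None
    out_dir: str | None = None
    resolution: float | None = None       # mm/pixel for raw-grid masks
    max_edge_mm: float = 0.5
    profile_n: int = 100
    scheme: str = "arclength"
    fractions: tuple | None = None
    half_width_mm: float = 2.5
    min_area_mm2: float = 0.0
    curvature_resample_mm: float = 2.0
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    metrics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def mark(self, stage: str, status: str, detail: str = ""):
        self.stages[stage] = {"status": status, "detail": detail}
        logger.info("[%s] %s %s", stage, status, detail)

    def warn(self, stage: str, message: str):
        self.warnings.append({"stage": stage, "message": message})
        logger.warning("[%s] %s", stage, message)

    def as_dict(self) -> dict:
        return {"stages": self.stages, "warnings": self.warnings,
                "metrics": self.metrics, "provenance": self.provenance}


STAGES = ("inputs", "meshing", "laplace", "thickness", "metrics", "subseg",
          "outputs")


@dataclass
class PipelineResult:
    report: RunReport
    mesh: CCMesh | None = None
    u: np.ndarray | None = None
    v: np.ndarray | None = None
    line: object = None
    profile: object = None
    metrics: object = None
    subseg: object = None


def run_pipeline(config: PipelineConfig, mask: np.ndarray | None = None,
                 landmarks: dict | None = None,
                 origin=(0.0, 0.0), slice_stack=None) -> PipelineResult:
    """Execute all stages; inputs may come from files (config paths) or be
    passed directly (mask/landmarks arguments take precedence)."""
    report = RunReport()
    report.provenance = {"config_hash": config.config_hash(),
                         "config": asdict(config)}
    result = PipelineResult(report=report)
    stage = "inputs"
    try:
        if mask is None and config.mask_path:
            data, affine = ccio.load_volume(config.mask_path)
            if data.ndim == 3:
                mid = data.shape[0] // 2
                mask = data[mid] > 0.5
            else:
                mask = data > 0.5
            if config.resolution is None:
                config.resolution = float(
                    np.linalg.norm(affine[:3, :3], axis=0)[1])
            origin = (float(affine[1, 3]), float(affine[2, 3]))
        if landmarks is None and config.landmarks_path:
            landmarks = ccio.load_landmarks(config.landmarks_path)
        if mask is None or landmarks is None:
            raise PipelineError(stage, "mask and landmarks are required")
        res = config.resolution if config.resolution else 1.0
        ac = np.asarray(landmarks["AC"], dtype=float)[:2]
        pc = np.asarray(landmarks["PC"], dtype=float)[:2]
        report.mark(stage, "ok")

        stage = "meshing"
        mesh = build_cc_mesh(np.asarray(mask) > 0, res, ac, pc,
                             max_edge_mm=config.max_edge_mm, origin=origin,
                             min_area_mm2=config.min_area_mm2)
        result.mesh = mesh
        report.mark(stage, "ok",
                    f"{mesh.n_vertices} vertices, {len(mesh.triangles)} "
                    "triangles")

        stage = "laplace"
        u = solve_laplace(mesh)
        v = conjugate_potential(mesh, u)
        result.u, result.v = u, v
        report.mark(stage, "ok")

        stage = "thickness"
        line = intercallosal_line(mesh, u, v)
        profile = thickness_profile(mesh, u, v, line, n=config.profile_n)
        n_missing = int((~profile.valid).sum())
        if n_missing:
            report.warn(stage, f"{n_missing} thickness samples flagged "
                        "missing")
        result.line, result.profile = line, profile
        report.mark(stage, "ok", f"{int(profile.valid.sum())} valid samples")

        stage = "metrics"
        curvature = line_curvature(line, config.curvature_resample_mm)
        slice_areas = spacing = None
        if slice_stack is not None:
            slice_areas = slice_areas_from_stack(
                slice_stack.slices, slice_stack.in_plane_resolution)
            spacing = slice_stack.slice_spacing
        metrics = compute_shape_metrics(
            mesh, profile, line, curvature, slice_areas=slice_areas,
            spacing=spacing, half_width=config.half_width_mm)
        result.metrics = metrics
        report.metrics = metrics.as_dict()
        report.mark(stage, "ok")

        stage = "subseg"
        sub = subsegment(mesh, config.scheme, v=v, line=line, ac=ac, pc=pc,
                         fractions=config.fractions)
        result.subseg = sub
        report.mark(stage, "ok", f"{sub.n_regions} regions")

        stage = "outputs"
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            ccio.save_mesh_off(out / "mesh.off", mesh)
            ccio.save_mesh_vtk(out / "fields.vtk", mesh,
                               point_data={"u": u, "v": v},
                               cell_data={"region": sub.face_labels})
            ccio.save_profile_tsv(out / "profile.tsv", profile.positions,
                                  profile.thickness)
            ccio.save_polylines_vtk(out / "level_paths.vtk",
                                    profile.level_paths)
            with open(out / "metrics.json", "w") as fh:
                json.dump(metrics.as_dict(), fh, indent=2)
            _write_tsv_row(out / "metrics.tsv", metrics.as_dict())
            np.savetxt(out / "subseg.tsv",
                       np.column_stack([np.arange(1, sub.n_regions + 1),
                                        sub.region_areas]),
                       delimiter="\t", header="region\tarea_mm2", comments="")
        report.mark(stage, "ok")
    except PipelineError:
        _mark_downstream(report, stage)
        raise
    except Exception as exc:
        report.mark(stage, "failed", str(exc))
        _mark_downstream(report, stage)
        raise PipelineError(stage, str(exc)) from exc
    return result


def _mark_downstream(report: RunReport, failed_stage: str):
    seen = False
    for st in STAGES:
        if st == failed_stage:
            seen = True
            if st not in report.stages:
                report.mark(st, "failed")
            continue
        if seen and st not in report.stages:
            report.mark(st, "skipped")


def _write_tsv_row(path, values: dict):
    keys = list(values)
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        fh.write("\t".join(f"{values[k]:.9g}" for k in keys) + "\n")


def write_report(report: RunReport, path):
    """JSON report with machine-readable stage statuses."""
    with open(path, "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
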