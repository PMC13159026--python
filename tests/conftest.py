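import numpy as np
import pytest

from ccmorph.laplace import (conjugate_potential, intercallosal_line,
                             solve_laplace, thickness_profile)
from ccmorph.meshing import Contour2D, mesh_from_contour
from ccmorph.synthdata import RibbonSpec, generate_ribbon, ribbon_contour

R_INNER = 10.0
R_OUTER = 15.0
RECT_L = 20.0
RECT_H = 8.0


def rectangle_spec():
    return RibbonSpec(kind="straight", length=RECT_L, thickness="constant",
                      thickness_params=(RECT_H / 2,))


def annulus_spec():
    return RibbonSpec(kind="arc", radius=(R_INNER + R_OUTER) / 2, span=np.pi,
                      thickness="constant",
                      thickness_params=((R_OUTER - R_INNER) / 2,))


def build_fields(mesh):
    u = solve_laplace(mesh)
    v = conjugate_potential(mesh, u)
    line = intercallosal_line(mesh, u, v)
    return u, v, line


@pytest.fixture(scope="session")
def rect_mesh():
    verts, lm = ribbon_contour(rectangle_spec())
    return mesh_from_contour(Contour2D(verts), lm["AC"], lm["PC"],
                             max_edge_mm=0.5)


@pytest.fixture(scope="session")
def rect_fields(rect_mesh):
    u, v, line = build_fields(rect_mesh)
    profile = thickness_profile(rect_mesh, u, v, line, n=100)
    return {"mesh": rect_mesh, "u": u, "v": v, "line": line,
            "profile": profile}


@pytest.fixture(scope="session")
def annulus_mesh():
    verts, lm = ribbon_contour(annulus_spec())
    return mesh_from_contour(Contour2D(verts), lm["AC"], lm["PC"],
                             max_edge_mm=0.25)


@pytest.fixture(scope="session")
def annulus_fields(annulus_mesh):
    u, v, line = build_fields(annulus_mesh)
    profile = thickness_profile(annulus_mesh, u, v, line, n=100)
    return {"mesh": annulus_mesh, "u": u, "v": v, "line": line,
            "profile": profile}


@pytest.fixture(scope="session")
def arc_ribbon_raster():
    spec = RibbonSpec(kind="arc", resolution=0.5, thickness="linear",
                      thickness_params=(2.0, 3.0))
    mask, origin, landmarks, truth = generate_ribbon(spec, seed=7)
    return {"spec": spec, "mask": mask, "origin": origin,
            "landmarks": landmarks, "truth": truth}
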