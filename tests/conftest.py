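"""Shared fixtures: analytic coax lines, coarse probe meshes, simple meshes."""

import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from mwablate import _fem
from mwablate.geometry import BoundaryTag, build_probe_geometry
from mwablate.materials import default_assignment, material_field
from mwablate.mesh import MeshControls, generate_mesh, rectangle_geometry
from mwablate.em import SourceSpec, solve_em

RI, RO = 0.135e-3, 0.335e-3


def make_coax(bottom_tag, length=20e-3, h=0.05e-3, hz=0.5e-3):
    """Straight coax fixture: PEC side walls, port on top, chosen far end."""
    geo = rectangle_geometry(RO - RI, length, region="coax_dielectric",
                             r0=RI, port=(RI, RO),
                             top_tag=BoundaryTag.PEC,
                             side_tag=BoundaryTag.PEC,
                             bottom_tag=bottom_tag,
                             inner_side_tag=BoundaryTag.PEC)
    ctl = MeshControls(h_fine=h, h_far=hz, grading=0.05, h_port=hz)
    mesh = generate_mesh(geo, ctl, tissue_props_37=(2.03, 0.0))
    return geo, mesh


@pytest.fixture(scope="session")
def coarse_controls():
    """Coarser-than-default mesh for cheap structural tests."""
    return MeshControls(h_fine=2e-4, h_far=3e-3, h_port=4e-4)


@pytest.fixture(scope="session")
def ss_geometry():
    return build_probe_geometry("SS")


@pytest.fixture(scope="session")
def ss_mesh(ss_geometry, coarse_controls):
    return generate_mesh(ss_geometry, coarse_controls)


@pytest.fixture(scope="session")
def ss_em(ss_geometry, ss_mesh):
    space = _fem.build_space(ss_mesh)
    T = np.full(ss_mesh.n_vertices, 37.0)
    props = material_field(ss_mesh, T, default_assignment())
    return solve_em(ss_mesh, props, SourceSpec(), space=space)


@pytest.fixture()
def disc_mesh():
    """Solid cylinder section (r, z) in [0, 10mm] x [0, 10mm], one region."""
    geo = rectangle_geometry(10e-3, 10e-3, region="tissue")
    ctl = MeshControls(h_fine=1e-3, h_far=1e-3, grading=0.5, h_port=1e-3)
    mesh = generate_mesh(geo, ctl, tissue_props_37=(1.0, 0.0))
    return geo, mesh
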