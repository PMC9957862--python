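"""Meshing: conformity, tagging, determinism, grading and interchange."""

import numpy as np
import pytest

from mwablate.geometry import BoundaryTag
from mwablate.mesh import (MeshControls, MeshingError, generate_mesh, read_msh,
                           rectangle_geometry, write_msh)


def test_unit_square_topology():
    """Euler formula V - E + F = 1 for a meshed disc-like domain."""
    geo = rectangle_geometry(1.0, 1.0)
    ctl = MeshControls(h_fine=0.25, h_far=0.25, grading=1.0, h_port=0.25)
    mesh = generate_mesh(geo, ctl, tissue_props_37=(1.0, 0.0))
    edges = np.sort(np.concatenate([mesh.triangles[:, [0, 1]],
                                    mesh.triangles[:, [1, 2]],
                                    mesh.triangles[:, [2, 0]]]), axis=1)
    n_edges = len(np.unique(edges, axis=0))
    assert mesh.n_vertices - n_edges + mesh.n_triangles == 1
    assert np.all(mesh.signed_areas() > 0)


def test_every_exterior_edge_tagged_exactly_once():
    geo = rectangle_geometry(1.0, 1.0)
    ctl = MeshControls(h_fine=0.25, h_far=0.25, grading=1.0, h_port=0.25)
    mesh = generate_mesh(geo, ctl, tissue_props_37=(1.0, 0.0))
    # exterior edges = edges referenced by exactly one triangle
    edges = np.sort(np.concatenate([mesh.triangles[:, [0, 1]],
                                    mesh.triangles[:, [1, 2]],
                                    mesh.triangles[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    exterior = {tuple(e) for e in uniq[counts == 1]}
    tagged = {tuple(sorted(e)) for e in mesh.boundary_edges}
    assert tagged == exterior
    assert len(mesh.boundary_edges) == len(mesh.boundary_tags)


def test_probe_mesh_conforming_and_tagged(ss_mesh):
    assert np.all(ss_mesh.signed_areas() > 0)
    # every region id maps to a geometry region
    assert set(np.unique(ss_mesh.region_id)) <= set(range(len(ss_mesh.region_names)))
    # port, absorbing, pec and axis edges all present
    for tag in BoundaryTag:
        assert len(ss_mesh.tag_edges(tag)) > 0, tag
    # no hanging nodes: all vertices used
    assert len(np.unique(ss_mesh.triangles)) == ss_mesh.n_vertices


def test_slot_neighbourhood_respects_h_fine(ss_geometry, ss_mesh):
    """Axis-aligned cell extents within 2 mm of the slot stay at h_fine."""
    controls_h = 2e-4  # coarse_controls h_fine
    slot = ss_geometry.region_rects["slot_fill"][0]
    cent = ss_mesh.vertices[ss_mesh.triangles].mean(axis=1)
    dz = np.maximum(np.maximum(slot.z0 - cent[:, 1], cent[:, 1] - slot.z1), 0.0)
    dr = np.maximum(cent[:, 0] - slot.r1, 0.0)
    near = np.hypot(dz, dr) < 2e-3
    p = ss_mesh.vertices[ss_mesh.triangles[near]]
    dr_ext = p[..., 0].max(axis=1) - p[..., 0].min(axis=1)
    dz_ext = p[..., 1].max(axis=1) - p[..., 1].min(axis=1)
    assert dr_ext.max() <= controls_h * 1.01
    assert dz_ext.max() <= controls_h * 1.01


def test_near_slot_zone_is_isotropically_well_shaped(ss_geometry):
    """Triangle quality in the refined near-slot zone at default controls."""
    mesh = generate_mesh(ss_geometry, MeshControls())
    slot = ss_geometry.region_rects["slot_fill"][0]
    zc = 0.5 * (slot.z0 + slot.z1)
    cent = mesh.vertices[mesh.triangles].mean(axis=1)
    near = (np.abs(cent[:, 1] - zc) < 1e-3) & (cent[:, 0] < 1.5e-3)
    assert near.sum() > 0
    assert mesh.min_angle(mask=near) >= 30.0


def test_wavelength_cap_in_tissue(ss_geometry, ss_mesh):
    """Max tissue element size obeys the in-tissue wavelength resolution cap."""
    from mwablate.mesh import _tissue_wavelength
    from mwablate.materials import LIVER_SIGMOID

    lam = _tissue_wavelength(2.45e9, LIVER_SIGMOID.permittivity(37.0),
                             LIVER_SIGMOID.conductivity(37.0))
    tissue = ss_mesh.region_id == ss_mesh.region_index("tissue")
    assert ss_mesh.element_sizes()[tissue].max() <= lam / 10.0


def test_refinement_scaling(ss_geometry):
    """Halving both size controls multiplies the vertex count by ~4 (2D)."""
    coarse = MeshControls(h_fine=3e-4, h_far=1.2e-3, h_port=6e-4)
    m1 = generate_mesh(ss_geometry, coarse)
    halved = MeshControls(h_fine=1.5e-4, h_far=0.6e-3, h_port=3e-4)
    m2 = generate_mesh(ss_geometry, halved)
    factor = m2.n_vertices / m1.n_vertices
    assert 3.0 <= factor <= 5.0


def test_meshing_is_deterministic(ss_geometry, coarse_controls):
    m1 = generate_mesh(ss_geometry, coarse_controls)
    m2 = generate_mesh(ss_geometry, coarse_controls)
    assert np.array_equal(m1.vertices, m2.vertices)
    assert np.array_equal(m1.triangles, m2.triangles)
    assert np.array_equal(m1.region_id, m2.region_id)
    assert np.array_equal(m1.boundary_tags, m2.boundary_tags)


def test_invalid_controls_rejected():
    with pytest.raises(MeshingError):
        MeshControls(h_fine=2e-3, h_far=1e-3).validate()
    with pytest.raises(MeshingError):
        MeshControls(wavelength_points=2).validate()


def test_msh_round_trip(tmp_path, ss_mesh):
    path = tmp_path / "probe.msh"
    write_msh(ss_mesh, path)
    back = read_msh(path)
    assert back.region_names == ss_mesh.region_names
    assert back.tag_names == ss_mesh.tag_names
    np.testing.assert_allclose(back.vertices, ss_mesh.vertices, rtol=0, atol=1e-12)
    assert np.array_equal(back.triangles, ss_mesh.triangles)
    assert np.array_equal(back.region_id, ss_mesh.region_id)
    assert np.array_equal(np.sort(back.boundary_tags), np.sort(ss_mesh.boundary_tags))
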