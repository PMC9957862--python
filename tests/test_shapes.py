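"""Shape extraction and circularity: unit shapes, Gaussian level sets."""

import numpy as np
import pytest
import shapely.affinity as sa
import shapely.geometry as sg
from hypothesis import given, settings, strategies as st

from mwablate.mesh import MeshControls, generate_mesh, rectangle_geometry
from mwablate.shapes import (EmptyShapeError, RasterGuardError, Shape2D,
                             extract_threshold_shape, shape_metrics)


def circle(radius=1.0, n=4096):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return sg.Polygon(np.column_stack([radius * np.cos(t), radius * np.sin(t)]))


class TestCircularity:
    def test_circle_is_one(self):
        m = shape_metrics(Shape2D([circle(0.37)]))
        assert m.circularity == pytest.approx(1.0, abs=1e-3)

    def test_unit_square(self):
        m = shape_metrics(Shape2D([sg.box(0, 0, 1, 1)]))
        assert m.circularity == pytest.approx(np.pi / 4, abs=1e-12)

    def test_two_by_one_rectangle(self):
        m = shape_metrics(Shape2D([sg.box(0, 0, 2, 1)]))
        assert m.circularity == pytest.approx(8 * np.pi / 36, abs=1e-12)

    def test_hole_subtracts_area_and_adds_perimeter(self):
        ring = sg.Polygon(sg.box(0, 0, 4, 4).exterior.coords,
                          [list(sg.box(1, 1, 2, 2).exterior.coords)])
        m = shape_metrics(Shape2D([ring]))
        assert m.area == pytest.approx(15.0)
        assert m.perimeter == pytest.approx(20.0)

    def test_disjoint_components_aggregate(self):
        m = shape_metrics(Shape2D([sg.box(0, 0, 1, 1), sg.box(3, 0, 4, 1)]))
        assert m.area == pytest.approx(2.0)
        assert m.perimeter == pytest.approx(8.0)
        assert m.circularity == pytest.approx(8 * np.pi / 64, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.floats(1e-4, 1e4))
    def test_scale_invariance(self, c):
        base = shape_metrics(Shape2D([sg.box(0, 0, 2, 1)])).circularity
        scaled = shape_metrics(
            Shape2D([sa.scale(sg.box(0, 0, 2, 1), c, c, origin=(0, 0))]))
        assert scaled.circularity == pytest.approx(base, rel=1e-9)

    def test_empty_shape_signalled(self):
        with pytest.raises(EmptyShapeError):
            shape_metrics(Shape2D([]))


class _GaussianSampler:
    """Analytic radial Gaussian field on the half plane (no mesh)."""

    def __init__(self, rc, zc, w):
        self.rc, self.zc, self.w = rc, zc, w

    def sample(self, r, z):
        return np.exp(-(((r - self.rc) ** 2 + (z - self.zc) ** 2) / self.w ** 2))


@pytest.fixture(scope="module")
def gauss_setup():
    geo = rectangle_geometry(40e-3, 80e-3, region="tissue")
    sampler = _GaussianSampler(rc=0.0, zc=40e-3, w=8e-3)
    return geo, sampler


class TestExtraction:
    def test_gaussian_level_set_radius(self, gauss_setup):
        """Extracted contour sits within one raster cell of the analytic circle."""
        geo, sampler = gauss_setup
        thr = 0.5
        raster = 2e-4
        shp = extract_threshold_shape(sampler, thr, geo, raster=raster)
        assert len(shp.polygons) == 1
        R = sampler.w * np.sqrt(-np.log(thr))  # analytic level radius
        xy = np.asarray(shp.polygons[0].exterior.coords)
        rad = np.hypot(xy[:, 0], xy[:, 1] - sampler.zc)
        assert np.max(np.abs(rad - R)) <= raster * 1.5

    def test_gaussian_metrics_near_circle(self, gauss_setup):
        geo, sampler = gauss_setup
        shp = extract_threshold_shape(sampler, 0.5, geo)
        m = shape_metrics(shp)
        R = sampler.w * np.sqrt(np.log(2))
        assert m.area == pytest.approx(np.pi * R ** 2, rel=0.01)
        assert m.circularity == pytest.approx(1.0, abs=5e-3)

    def test_raster_halving_converges(self, gauss_setup):
        geo, sampler = gauss_setup
        a1 = shape_metrics(extract_threshold_shape(sampler, 0.5, geo, raster=4e-4)).area
        a2 = shape_metrics(extract_threshold_shape(sampler, 0.5, geo, raster=2e-4)).area
        assert abs(a1 - a2) / a2 < 0.01

    def test_mirror_symmetry_exact(self, gauss_setup):
        geo, sampler = gauss_setup
        shp = extract_threshold_shape(sampler, 0.5, geo)
        xy = np.asarray(shp.polygons[0].exterior.coords)
        mirrored = sg.Polygon(np.column_stack([-xy[:, 0], xy[:, 1]]))
        assert mirrored.symmetric_difference(shp.polygons[0]).area < 1e-16

    def test_threshold_above_maximum_is_empty(self, gauss_setup):
        geo, sampler = gauss_setup
        shp = extract_threshold_shape(sampler, 2.0, geo)
        assert shp.is_empty

    def test_constant_field_fills_mirrored_domain(self, gauss_setup):
        geo, _ = gauss_setup

        class Const:
            def sample(self, r, z):
                return np.full(np.shape(r), 3.0)

        shp = extract_threshold_shape(Const(), 1.5, geo, raster=4e-4)
        m = shape_metrics(shp)
        full = 2 * 40e-3 * 80e-3  # mirrored cross-section of the whole box
        assert m.area == pytest.approx(full, rel=0.02)

    def test_raster_guard(self, gauss_setup):
        geo, sampler = gauss_setup
        with pytest.raises(RasterGuardError):
            extract_threshold_shape(sampler, 0.5, geo, raster=5e-6)
        with pytest.raises(ValueError):
            extract_threshold_shape(sampler, -1.0, geo)


def test_probe_band_excluded_from_sar_shape(ss_geometry, ss_em):
    """The thresholded SAR shape never enters the probe band |x| < r_catheter."""
    from mwablate.shapes import ElementFieldSampler

    mesh = ss_em.mesh
    tissue = np.nonzero(mesh.region_id == mesh.region_index("tissue"))[0]
    samp = ElementFieldSampler(mesh, ss_em.Qs, elems=tissue)
    shp = extract_threshold_shape(samp, 1e3, ss_geometry, raster=4e-4)
    assert not shp.is_empty
    rc = ss_geometry.dims.r_catheter
    tip = ss_geometry.domain.tip_z(ss_geometry.dims)
    band = sg.box(-rc + 1e-3 * rc, 0, rc - 1e-3 * rc, tip - 1e-3)
    inside = sum(p.intersection(band).area for p in shp.polygons)
    assert inside <= 2 * (2 * rc) * 4e-4  # at most a raster-cell sliver
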