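"""Isocontour shape extraction and circularity metrics.

A thresholded field region {field >= threshold} in the axisymmetric tissue
half-plane is mirrored about the axis into a full (x, z) cross-section and
measured as a 2D shape: total area, total perimeter (including holes and
every disjoint component), and circularity

    circularity = 4 pi Area / Perimeter^2,

which is 1 for a circle and < 1 for anything else.  Extraction rasterises
the field on a uniform grid (default 0.2 mm), traces the threshold isoline
by marching squares with linear interpolation, and closes shapes along the
probe surface and domain edges.  The band occupied by the probe
(|x| < r_catheter over the inserted length) is excluded; where the region
abuts the catheter that interface contributes to the perimeter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely.geometry as sg
from skimage import measure as _skmeasure

from . import _fem

__all__ = ["Shape2D", "ShapeMetrics", "EmptyShapeError", "RasterGuardError",
           "extract_threshold_shape", "shape_metrics", "mesh_trifinder",
           "ElementFieldSampler", "NodalFieldSampler"]

_MIN_RASTER = 10e-6


def mesh_trifinder(mesh):
    """Build (and cache per mesh object) a matplotlib triangle point locator."""
    finder = getattr(mesh, "_trifinder_cache", None)
    if finder is None:
        import matplotlib.tri as mtri

        tri = mtri.Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1],
                                 mesh.triangles)
        finder = tri.get_trifinder()
        mesh._trifinder_cache = finder
        mesh._triangulation_cache = tri
    return finder


class EmptyShapeError(ValueError):
    """Metrics requested for an empty thresholded shape."""


class RasterGuardError(ValueError):
    """Raster finer than the resource guard allows."""


@dataclass
class ShapeMetrics:
    area: float         # m^2
    perimeter: float    # m
    circularity: float  # dimensionless, in (0, 1] up to polygonal tolerance


@dataclass
class Shape2D:
    """Closed simple polygons (with holes) in the mirrored (x, z) plane."""

    polygons: list          # list of shapely Polygon
    threshold: float = np.nan
    raster: float = np.nan

    @property
    def is_empty(self) -> bool:
        return len(self.polygons) == 0

    @property
    def half_plane_area(self) -> float:
        """Area of the x >= 0 half of the mirrored shape (for transparency)."""
        return sum(p.area for p in self.polygons) / 2.0

    def to_wkt(self) -> str:
        return sg.MultiPolygon(self.polygons).wkt if self.polygons else "MULTIPOLYGON EMPTY"


def shape_metrics(shape: Shape2D) -> ShapeMetrics:
    """Total area, perimeter and circularity of a (possibly disjoint) shape.

    Disjoint components are aggregated: area and perimeter are summed over
    all components (holes subtract area, their rims add perimeter) before
    the circularity is formed.
    """
    if shape.is_empty:
        raise EmptyShapeError("shape is empty; metrics undefined")
    area = sum(p.area for p in shape.polygons)
    perim = sum(p.length for p in shape.polygons)
    if perim <= 0 or area <= 0:
        raise EmptyShapeError("degenerate shape; metrics undefined")
    return ShapeMetrics(area=area, perimeter=perim,
                        circularity=4 * np.pi * area / perim ** 2)


class ElementFieldSampler:
    """Point sampler of a per-element (piecewise constant) field.

    Points outside the mesh, or inside elements excluded by ``elems``,
    sample as NaN.
    """

    def __init__(self, mesh, values, elems=None, finder=None):
        self.mesh = mesh
        self.values = np.asarray(values, float)
        if self.values.shape[0] != mesh.n_triangles:
            raise ValueError("one value per element required")
        self._finder = finder if finder is not None else mesh_trifinder(mesh)
        self._mask = None
        if elems is not None:
            self._mask = np.zeros(mesh.n_triangles, bool)
            self._mask[np.asarray(elems)] = True

    def sample(self, r, z):
        r = np.asarray(r, float)
        z = np.asarray(z, float)
        el = self._finder(r, z)
        out = np.full(el.shape, np.nan)
        ok = el >= 0
        if self._mask is not None:
            ok &= np.where(el >= 0, self._mask[np.clip(el, 0, None)], False)
        out[ok] = self.values[el[ok]]
        return out


class NodalFieldSampler:
    """Point sampler of a P2 nodal field (quadratic interpolation)."""

    def __init__(self, mesh, space, nodal, elems=None, finder=None):
        self.mesh = mesh
        self.space = space
        self.nodal = np.asarray(nodal, float)
        self._finder = finder if finder is not None else mesh_trifinder(mesh)
        self._mask = None
        if elems is not None:
            self._mask = np.zeros(mesh.n_triangles, bool)
            self._mask[np.asarray(elems)] = True

    def sample(self, r, z):
        r = np.asarray(r, float)
        z = np.asarray(z, float)
        el = self._finder(r, z)
        out = np.full(el.shape, np.nan)
        ok = el >= 0
        if self._mask is not None:
            ok &= np.where(el >= 0, self._mask[np.clip(el, 0, None)], False)
        if not np.any(ok):
            return out
        eidx = el[ok]
        tri = self.mesh.triangles[eidx]
        p0 = self.mesh.vertices[tri[:, 0]]
        J = np.stack([self.mesh.vertices[tri[:, 1]] - p0,
                      self.mesh.vertices[tri[:, 2]] - p0], axis=2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        d = np.stack([r[ok] - p0[:, 0], z[ok] - p0[:, 1]], axis=1)
        xi = (J[:, 1, 1] * d[:, 0] - J[:, 0, 1] * d[:, 1]) / detJ
        eta = (-J[:, 1, 0] * d[:, 0] + J[:, 0, 0] * d[:, 1]) / detJ
        lam = np.stack([1 - xi - eta, xi, eta], axis=1)
        N, _ = _fem._p2_shapes(lam)
        out[ok] = np.einsum("pi,pi->p", N, self.nodal[self.space.tri_dofs[eidx]])
        return out


def extract_threshold_shape(sampler, threshold: float, geometry,
                            raster: float = 2.0e-4) -> Shape2D:
    """Mirrored polygonal region {field >= threshold} within tissue.

    ``sampler`` provides ``sample(r, z) -> values`` (NaN outside its
    domain); ``geometry`` supplies the tissue bounding box and the probe
    band to exclude.  An empty shape (threshold above the field maximum) is
    returned as such, not raised.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if raster < _MIN_RASTER:
        raise RasterGuardError(f"raster {raster} finer than {_MIN_RASTER} guard")

    b = geometry.bbox
    nx = int(np.ceil((b.r1 - b.r0) / raster)) + 1
    nz = int(np.ceil((b.z1 - b.z0) / raster)) + 1
    xs = np.linspace(b.r0, b.r1, nx)
    zs = np.linspace(b.z0, b.z1, nz)
    X, Zg = np.meshgrid(xs, zs, indexing="ij")
    vals = sampler.sample(X.ravel(), Zg.ravel()).reshape(nx, nz)

    # mask: non-tissue sample points (probe band, holes) forced well below
    # threshold so contours close along the probe surface
    finite = np.isfinite(vals)
    scale = np.nanmax(np.abs(vals)) if np.any(finite) else 1.0
    low = -max(abs(threshold), scale, 1.0)
    vals[~finite] = low

    if np.nanmax(vals) < threshold:
        return Shape2D(polygons=[], threshold=threshold, raster=raster)

    # mirror about the axis: x in [-R, R]; column 0 is the axis
    full = np.concatenate([vals[:0:-1], vals], axis=0)
    x_full = np.concatenate([-xs[:0:-1], xs])
    # pad below `low` so every contour closes inside the raster
    padded = np.pad(full, 1, constant_values=2 * low)

    contours = _skmeasure.find_contours(padded, level=threshold)
    if not contours:
        return Shape2D(polygons=[], threshold=threshold, raster=raster)

    dx = xs[1] - xs[0]
    dz = zs[1] - zs[0]
    rings = []
    for c in contours:
        # index space -> physical; padding shifts indices by 1
        px = np.interp(c[:, 0] - 1, np.arange(len(x_full)), x_full)
        pz = np.interp(c[:, 1] - 1, np.arange(len(zs)), zs)
        ring = sg.Polygon(np.column_stack([px, pz]))
        if ring.is_valid and ring.area > (0.5 * dx * dz):
            rings.append(ring)
    if not rings:
        return Shape2D(polygons=[], threshold=threshold, raster=raster)

    # nest rings into polygons with holes (even-odd by containment depth)
    rings.sort(key=lambda p: p.area, reverse=True)
    depth = []
    for i, ring in enumerate(rings):
        d = sum(1 for j in range(i) if rings[j].contains(ring))
        depth.append(d)
    polys = []
    for i, ring in enumerate(rings):
        if depth[i] % 2 == 0:
            holes = [rings[j].exterior.coords for j in range(len(rings))
                     if depth[j] == depth[i] + 1
                     and rings[i].contains(rings[j])]
            polys.append(sg.Polygon(ring.exterior.coords, holes))
    return Shape2D(polygons=polys, threshold=threshold, raster=raster)
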