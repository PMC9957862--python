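"""Deterministic graded triangular meshing of the rectilinear (r, z) geometry.

All material interfaces of the probe geometry are axis-aligned, so the mesh
is generated from a tensor product of graded r- and z-lines that contains
every interface coordinate exactly; each rectangular cell is classified by
its centre and split into two triangles.  This makes the mesh conforming,
bit-reproducible, and element-wise constant in material, at the cost of
allowing anisotropic cells away from the refinement zones.  The anisotropy
is aligned with the field anisotropy (thin coax layers vary rapidly only in
r; the near-slot/tip zone is isotropically fine), which nodal elements
handle well.

Line placement within each mandatory interval follows the inverse-CDF of a
1/size density, so grading is smooth and refinement scales predictably.
"""

from __future__ import annotations

from dataclasses import dataclass
import io

import numpy as np

from .geometry import BoundaryTag, GeometryModel

__all__ = ["MeshControls", "TriangleMesh", "MeshingError", "generate_mesh",
           "rectangle_geometry", "write_msh", "read_msh"]

C0 = 299_792_458.0


class MeshingError(RuntimeError):
    pass


@dataclass
class MeshControls:
    """Mesh size controls, metres.

    ``h_fine`` applies near slots/tip, ``h_far`` at the domain boundary,
    ``grading`` is the growth of target size per unit distance from a
    feature, and ``wavelength_points`` caps the element size in tissue to
    lambda_tissue / wavelength_points at 37 degC.
    """

    h_fine: float = 1.0e-4
    h_far: float = 2.0e-3
    grading: float = 0.35
    wavelength_points: float = 10.0
    h_port: float = 2.5e-4  # axial size at the input plane (port integral accuracy)

    def validate(self) -> None:
        if not (0 < self.h_fine <= self.h_far):
            raise MeshingError("require 0 < h_fine <= h_far")
        if self.wavelength_points < 5:
            raise MeshingError("wavelength_points must be >= 5")
        if self.grading <= 0:
            raise MeshingError("grading must be positive")


@dataclass
class TriangleMesh:
    """Conforming triangulation with per-triangle region and tagged edges."""

    vertices: np.ndarray          # (n, 2) float, columns (r, z)
    triangles: np.ndarray         # (m, 3) int, counter-clockwise
    region_id: np.ndarray         # (m,) int into region_names
    region_names: list[str]
    boundary_edges: np.ndarray    # (k, 2) int vertex pairs
    boundary_tags: np.ndarray     # (k,) int into tag_names
    tag_names: list[str]
    boundary_elem: np.ndarray     # (k,) int: triangle adjacent to each boundary edge

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def signed_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                      - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))

    def min_angle(self, mask: np.ndarray | None = None) -> float:
        """Smallest interior angle (degrees), optionally over a triangle mask."""
        p = self.vertices[self.triangles if mask is None else self.triangles[mask]]
        angs = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return float(np.min(angs))

    def region_index(self, name: str) -> int:
        return self.region_names.index(name)

    def element_sizes(self) -> np.ndarray:
        """Longest edge per triangle."""
        p = self.vertices[self.triangles]
        e = np.stack([np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
                      np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
                      np.linalg.norm(p[:, 0] - p[:, 2], axis=1)])
        return e.max(axis=0)

    def tag_edges(self, tag: BoundaryTag) -> np.ndarray:
        idx = self.tag_names.index(tag.value)
        return np.nonzero(self.boundary_tags == idx)[0]


def _graded_lines(a: float, b: float, size: "callable", n_sample: int = 512) -> np.ndarray:
    """Distribute lines in [a, b] following density 1/size via inverse CDF."""
    if b - a <= 0:
        raise MeshingError("empty interval")
    zs = np.linspace(a, b, n_sample)
    dens = 1.0 / np.maximum(size(zs), 1e-12)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(zs))])
    n = max(1, int(round(cdf[-1])))
    targets = np.linspace(0.0, cdf[-1], n + 1)
    lines = np.interp(targets, cdf, zs)
    lines[0], lines[-1] = a, b
    return lines


def _tissue_wavelength(frequency: float, eps_r: float, sigma: float) -> float:
    eps0 = 8.8541878128e-12
    omega = 2 * np.pi * frequency
    k0 = omega / C0
    n_eff = np.sqrt(complex(eps_r, -sigma / (omega * eps0)))
    return float(2 * np.pi / (k0 * n_eff.real))


def generate_mesh(geometry: GeometryModel, controls: MeshControls | None = None,
                  frequency: float = 2.45e9,
                  tissue_props_37: tuple[float, float] | None = None) -> TriangleMesh:
    """Mesh a geometry model with graded refinement near slots and tip.

    ``tissue_props_37`` is the (eps_r, sigma) pair used for the in-tissue
    wavelength cap; by default the package's liver model at 37 degC.
    """
    controls = controls or MeshControls()
    controls.validate()

    if tissue_props_37 is None:
        from .materials import LIVER_SIGMOID
        tissue_props_37 = (LIVER_SIGMOID.permittivity(37.0), LIVER_SIGMOID.conductivity(37.0))
    lam = _tissue_wavelength(frequency, *tissue_props_37)
    # cell diagonal ~ sqrt(hr^2 + hz^2); cap each direction so it obeys the limit
    h_cap = min(controls.h_far, 0.995 * lam / controls.wavelength_points / np.sqrt(2.0))

    feats_z = np.array(geometry.feature_z())
    slots = geometry.slot_z_intervals()
    rp = geometry.probe_radius()
    guard = 2.0e-3 if rp > 0 else 0.0  # h_fine plateau radius around slots/probe tip

    def size_z(z):
        z = np.atleast_1d(z)
        d = np.min(np.abs(np.subtract.outer(z, feats_z)), axis=1)
        s = controls.h_fine + controls.grading * d
        for z0, z1 in slots:
            d_slot = np.maximum(np.maximum(z0 - z, z - z1), 0.0)
            s = np.minimum(s, controls.h_fine
                           + controls.grading * np.maximum(d_slot - guard, 0.0))
        s = np.minimum(s, controls.h_port + controls.grading * np.abs(
            z - geometry.bbox.z0))
        return np.clip(s, controls.h_fine, h_cap)

    def size_r(r):
        r = np.atleast_1d(r)
        d = np.maximum(r - rp, 0.0)
        if slots:
            d = np.maximum(d - guard, 0.0)  # keep h_fine out to the slot plateau
        s = controls.h_fine + controls.grading * d
        return np.clip(s, controls.h_fine, h_cap)

    # --- line sets --------------------------------------------------------
    def build_lines(mandatory, size, fine_zone_hi=None):
        lines = [np.array([mandatory[0]])]
        for a, b in zip(mandatory[:-1], mandatory[1:]):
            if b - a < 1e-9:
                continue
            if fine_zone_hi is not None and b <= fine_zone_hi + 1e-12:
                # inside the probe: fixed subdivision, >= 2 cells per layer
                n = max(2, int(np.ceil((b - a) / max(controls.h_fine, 1e-4))))
                seg = np.linspace(a, b, n + 1)
            else:
                seg = _graded_lines(a, b, size)
            lines.append(seg[1:])
        return np.unique(np.concatenate(lines))

    r_lines = build_lines(geometry.mandatory_r_lines(), size_r,
                          fine_zone_hi=rp if rp > 0 else None)
    z_lines = build_lines(geometry.mandatory_z_lines(), size_z)

    # --- cells, classification, triangles ---------------------------------
    nr, nz = len(r_lines), len(z_lines)
    rr, zz = np.meshgrid(r_lines, z_lines, indexing="ij")
    vid = np.arange(nr * nz).reshape(nr, nz)

    region_names = sorted(geometry.region_rects)
    name_to_id = {n: i for i, n in enumerate(region_names)}

    rc_centres = 0.5 * (r_lines[:-1] + r_lines[1:])
    zc_centres = 0.5 * (z_lines[:-1] + z_lines[1:])

    tris, regs = [], []
    cell_region = np.full((nr - 1, nz - 1), -1, dtype=int)
    for i in range(nr - 1):
        for j in range(nz - 1):
            name = geometry.classify(rc_centres[i], zc_centres[j])
            if name is None:
                continue
            cell_region[i, j] = name_to_id[name]
    occupied = cell_region >= 0
    ii, jj = np.nonzero(occupied)
    v00 = vid[ii, jj]
    v10 = vid[ii + 1, jj]
    v11 = vid[ii + 1, jj + 1]
    v01 = vid[ii, jj + 1]
    # split each quad along the (v00, v11) diagonal; CCW in the (r, z) plane
    t1 = np.stack([v00, v10, v11], axis=1)
    t2 = np.stack([v00, v11, v01], axis=1)
    triangles = np.concatenate([t1, t2])
    region_id = np.concatenate([cell_region[ii, jj]] * 2)

    vertices = np.stack([rr.ravel(), zz.ravel()], axis=1)
    # drop unused vertices (inside holes)
    used = np.unique(triangles)
    remap = -np.ones(len(vertices), dtype=int)
    remap[used] = np.arange(len(used))
    vertices = vertices[used]
    triangles = remap[triangles]

    sa = TriangleMesh(vertices, triangles, region_id, region_names,
                      np.empty((0, 2), int), np.empty(0, int), [], np.empty(0, int))
    if np.any(sa.signed_areas() <= 0):
        raise MeshingError("degenerate or inverted triangle produced")

    # --- boundary edges ----------------------------------------------------
    edges = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]],
                            triangles[:, [2, 0]]])
    owner = np.tile(np.arange(len(triangles)), 3)
    key = np.sort(edges, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key_s, edges_s, owner_s = key[order], edges[order], owner[order]
    dup_prev = np.all(key_s[1:] == key_s[:-1], axis=1)
    is_boundary = np.ones(len(key_s), bool)
    is_boundary[1:][dup_prev] = False
    is_boundary[:-1][dup_prev] = False
    b_edges = edges_s[is_boundary]
    b_elem = owner_s[is_boundary]

    mids = 0.5 * (vertices[b_edges[:, 0]] + vertices[b_edges[:, 1]])
    tag_names = [t.value for t in BoundaryTag]
    tag_idx = {t: i for i, t in enumerate(tag_names)}
    b_tags = np.array([tag_idx[geometry.edge_tag(rm, zm).value] for rm, zm in mids])

    return TriangleMesh(vertices, triangles, region_id, region_names,
                        b_edges, b_tags, tag_names, b_elem)


def rectangle_geometry(width: float, height: float, *, region: str = "tissue",
                       port: tuple[float, float] | None = None,
                       top_tag: BoundaryTag = BoundaryTag.OUTER_ABSORBING,
                       side_tag: BoundaryTag = BoundaryTag.OUTER_ABSORBING,
                       bottom_tag: BoundaryTag = BoundaryTag.OUTER_ABSORBING,
                       r0: float = 0.0,
                       inner_side_tag: BoundaryTag | None = None) -> GeometryModel:
    """Single-region rectangular fixture (unit squares, straight coax, discs)."""
    from .geometry import Rect

    if inner_side_tag is None:
        inner_side_tag = BoundaryTag.AXIS if r0 == 0.0 else BoundaryTag.PEC
    return GeometryModel(
        region_rects={region: [Rect(r0, r0 + width, 0.0, height)]},
        conductor_rects={},
        bbox=Rect(r0, r0 + width, 0.0, height),
        port=port if port is not None else (np.nan, np.nan),
        top_tag=top_tag, side_tag=side_tag, bottom_tag=bottom_tag,
        inner_side_tag=inner_side_tag,
    )


# --- Gmsh ASCII v2.2 interchange ------------------------------------------

def write_msh(mesh: TriangleMesh, path) -> None:
    """Write the mesh in Gmsh 2.2 ASCII with physical groups.

    Surface physical ids are 1-based region indices; line physical ids are
    1000 + boundary tag index, so external meshers/viewers can substitute.
    """
    buf = io.StringIO()
    buf.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
    buf.write("$PhysicalNames\n")
    n_names = len(mesh.region_names) + len(mesh.tag_names)
    buf.write(f"{n_names}\n")
    for i, name in enumerate(mesh.region_names):
        buf.write(f'2 {i + 1} "{name}"\n')
    for i, name in enumerate(mesh.tag_names):
        buf.write(f'1 {1000 + i} "{name}"\n')
    buf.write("$EndPhysicalNames\n$Nodes\n")
    buf.write(f"{mesh.n_vertices}\n")
    for i, (r, z) in enumerate(mesh.vertices):
        buf.write(f"{i + 1} {r:.16g} {z:.16g} 0\n")
    buf.write("$EndNodes\n$Elements\n")
    buf.write(f"{mesh.n_triangles + len(mesh.boundary_edges)}\n")
    eid = 1
    for (a, b), t in zip(mesh.boundary_edges, mesh.boundary_tags):
        buf.write(f"{eid} 1 2 {1000 + t} {1000 + t} {a + 1} {b + 1}\n")
        eid += 1
    for (a, b, c), rg in zip(mesh.triangles, mesh.region_id):
        buf.write(f"{eid} 2 2 {rg + 1} {rg + 1} {a + 1} {b + 1} {c + 1}\n")
        eid += 1
    buf.write("$EndElements\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_msh(path) -> TriangleMesh:
    """Read a Gmsh 2.2 ASCII mesh written by :func:`write_msh`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    region_names: list[str] = []
    tag_names: list[str] = []
    verts = []
    tris, regs, bed, btag = [], [], [], []
    while i < len(lines):
        ln = lines[i]
        if ln == "$PhysicalNames":
            n = int(lines[i + 1])
            surf, lin = {}, {}
            for k in range(n):
                dim, pid, name = lines[i + 2 + k].split(maxsplit=2)
                name = name.strip('"')
                (surf if dim == "2" else lin)[int(pid)] = name
            region_names = [surf[k] for k in sorted(surf)]
            tag_names = [lin[k] for k in sorted(lin)]
            i += n + 2
        elif ln == "$Nodes":
            n = int(lines[i + 1])
            for k in range(n):
                parts = lines[i + 2 + k].split()
                verts.append((float(parts[1]), float(parts[2])))
            i += n + 2
        elif ln == "$Elements":
            n = int(lines[i + 1])
            for k in range(n):
                parts = [int(x) for x in lines[i + 2 + k].split()]
                etype, ntags = parts[1], parts[2]
                phys = parts[3]
                nodes = parts[3 + ntags:]
                if etype == 1:
                    bed.append((nodes[0] - 1, nodes[1] - 1))
                    btag.append(phys - 1000)
                elif etype == 2:
                    tris.append((nodes[0] - 1, nodes[1] - 1, nodes[2] - 1))
                    regs.append(phys - 1)
            i += n + 2
        else:
            i += 1
    mesh = TriangleMesh(np.array(verts), np.array(tris, int), np.array(regs, int),
                        region_names, np.array(bed, int).reshape(-1, 2),
                        np.array(btag, int), tag_names,
                        np.full(len(bed), -1, int))
    return mesh
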