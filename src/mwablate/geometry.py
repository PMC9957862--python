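"""Axisymmetric probe-in-tissue geometry for microwave ablation antennas.

The computational domain is the (r, z) half-plane section of a tissue
cylinder with an interstitial coaxial probe inserted along the axis of
symmetry.  z increases *downward* along the insertion direction: the probe
enters through the top face (z = 0) and its tip sits at z = insertion.
All lengths are stored in metres.

Because every probe feature is a body of revolution with flat annular
faces, every material region is an axis-aligned rectangle (or a union of
them) in the (r, z) plane.  The geometry model therefore stores regions as
rectangle lists; polygon views (for export and area checks) are derived.

Four probe concepts are supported:

* ``monopole`` (M) - the outer conductor is removed over a terminal
  section, leaving a bare dielectric-coated monopole; open tip.
* ``single_slot`` (SS) - one circumferential gap in the outer conductor
  near the short-circuited tip.
* ``dual_slot`` (DS) - two such gaps separated axially.
* ``sleeve_single_slot`` (SSS) - the SS layout plus a floating conducting
  sleeve inside the catheter, separated from the outer conductor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "ProbeConcept",
    "ProbeDimensions",
    "DomainSpec",
    "Rect",
    "BoundaryTag",
    "GeometryModel",
    "GeometryError",
    "default_dimensions",
    "build_probe_geometry",
]


class GeometryError(ValueError):
    """Raised when probe/domain parameters produce an invalid geometry."""


class ProbeConcept(str, enum.Enum):
    MONOPOLE = "monopole"
    SINGLE_SLOT = "single_slot"
    DUAL_SLOT = "dual_slot"
    SLEEVE_SINGLE_SLOT = "sleeve_single_slot"

    @classmethod
    def parse(cls, value: "str | ProbeConcept") -> "ProbeConcept":
        """Accept enum values, long names, or the field's short codes M/SS/DS/SSS."""
        if isinstance(value, ProbeConcept):
            return value
        short = {"M": cls.MONOPOLE, "SS": cls.SINGLE_SLOT,
                 "DS": cls.DUAL_SLOT, "SSS": cls.SLEEVE_SINGLE_SLOT}
        s = str(value).strip()
        if s.upper() in short:
            return short[s.upper()]
        return cls(s.lower())

    @property
    def short(self) -> str:
        return {ProbeConcept.MONOPOLE: "M", ProbeConcept.SINGLE_SLOT: "SS",
                ProbeConcept.DUAL_SLOT: "DS",
                ProbeConcept.SLEEVE_SINGLE_SLOT: "SSS"}[self]


MM = 1e-3


@dataclass
class ProbeDimensions:
    """Cross-sectional and axial dimensions of a probe, metres.

    The coax radii / slot width / sleeve thickness / probe length are the
    common values shared by all four concepts; the remaining offsets are
    concept specific and configurable.
    """

    r_inner: float = 0.135 * MM          # inner conductor outer radius
    r_dielectric: float = 0.335 * MM     # coax dielectric outer radius
    r_outer: float = 0.46 * MM           # outer conductor outer radius
    r_catheter: float = 0.895 * MM       # catheter outer radius
    slot_width: float = 1.0 * MM
    sleeve_thickness: float = 0.15 * MM
    probe_length: float = 70.0 * MM
    slot_tip_offset: float = 5.0 * MM    # slot centre to probe tip
    slot_separation: float = 8.0 * MM    # DS only, centre to centre
    sleeve_gap: float = 0.1 * MM         # radial gap outer conductor -> sleeve
    sleeve_start_offset: float = 10.0 * MM  # slot centre up to sleeve lower end
    sleeve_length: float = 15.0 * MM
    monopole_exposed_length: float = 10.0 * MM
    tip_cap_thickness: float = 0.5 * MM  # short-circuit plug (slotted concepts)

    def validate(self, concept: ProbeConcept) -> None:
        if not (0 < self.r_inner < self.r_dielectric < self.r_outer < self.r_catheter):
            raise GeometryError(
                "coax radii must satisfy 0 < r_inner < r_dielectric < r_outer < r_catheter")
        for name in ("slot_width", "probe_length", "tip_cap_thickness"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        L = self.probe_length
        if concept in (ProbeConcept.SINGLE_SLOT, ProbeConcept.DUAL_SLOT,
                       ProbeConcept.SLEEVE_SINGLE_SLOT):
            lo = self.slot_tip_offset - self.slot_width / 2
            if lo <= self.tip_cap_thickness:
                raise GeometryError("slot overlaps the tip cap: "
                                    "slot_tip_offset too small for slot_width")
            if self.slot_tip_offset + self.slot_width / 2 >= L:
                raise GeometryError("slot lies outside the probe length")
        if concept is ProbeConcept.DUAL_SLOT:
            if self.slot_separation < self.slot_width:
                raise GeometryError(
                    "dual-slot separation smaller than slot width: slots overlap")
            if self.slot_tip_offset + self.slot_separation + self.slot_width / 2 >= L:
                raise GeometryError("upper slot lies outside the probe length")
        if concept is ProbeConcept.SLEEVE_SINGLE_SLOT:
            if self.sleeve_thickness <= 0 or self.sleeve_gap <= 0:
                raise GeometryError("sleeve thickness and gap must be positive")
            if self.r_outer + self.sleeve_gap + self.sleeve_thickness >= self.r_catheter:
                raise GeometryError("sleeve does not fit inside the catheter wall")
            sl_hi = self.slot_tip_offset + self.sleeve_start_offset  # from tip, lower end
            sl_lo = sl_hi + self.sleeve_length                        # upper end
            if sl_hi <= self.slot_tip_offset + self.slot_width / 2:
                raise GeometryError("sleeve collides with the slot")
            if sl_lo >= L:
                raise GeometryError("sleeve extends beyond the probe input")
        if concept is ProbeConcept.MONOPOLE:
            if not (0 < self.monopole_exposed_length < L):
                raise GeometryError("monopole exposed length must lie within the probe")


@dataclass
class DomainSpec:
    """Tissue cylinder and probe placement.

    ``insertion`` is the depth of the probe tip below the tissue top face;
    by default the probe is fully inserted (tip at z = probe_length).
    """

    tissue_height: float = 80.0 * MM
    tissue_radius: float = 40.0 * MM
    insertion: float | None = None  # default: probe_length

    def tip_z(self, dims: ProbeDimensions) -> float:
        return self.insertion if self.insertion is not None else dims.probe_length

    def validate(self, dims: ProbeDimensions, clearance: float = 2e-3) -> None:
        if self.tissue_height <= 0 or self.tissue_radius <= 0:
            raise GeometryError("tissue dimensions must be positive")
        tip = self.tip_z(dims)
        if tip >= self.tissue_height - clearance:
            raise GeometryError("probe tip too close to the tissue bottom face")
        if dims.r_catheter >= self.tissue_radius - clearance:
            raise GeometryError("catheter too close to the tissue outer radius")


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle [r0, r1] x [z0, z1] in the meridian plane."""

    r0: float
    r1: float
    z0: float
    z1: float

    def __post_init__(self):
        if not (self.r1 > self.r0 and self.z1 > self.z0):
            raise GeometryError(f"degenerate rectangle {self!r}")

    @property
    def area(self) -> float:
        return (self.r1 - self.r0) * (self.z1 - self.z0)

    def contains(self, r: float, z: float) -> bool:
        return self.r0 <= r <= self.r1 and self.z0 <= z <= self.z1

    def polygon(self) -> list[tuple[float, float]]:
        return [(self.r0, self.z0), (self.r1, self.z0),
                (self.r1, self.z1), (self.r0, self.z1)]


class BoundaryTag(str, enum.Enum):
    PORT = "port"
    OUTER_ABSORBING = "outer_absorbing"
    PEC = "pec"
    AXIS = "axis"


@dataclass
class GeometryModel:
    """Tagged rectilinear regions and boundary rules of the EM domain.

    ``region_rects`` maps material region names (tissue, coax_dielectric,
    catheter, slot_fill, sleeve_gap_fill) to rectangle lists; conductors
    (inner/outer conductor, sleeve, tip cap) are excluded holes whose
    exposed surfaces carry the PEC tag.
    """

    region_rects: dict[str, list[Rect]]
    conductor_rects: dict[str, list[Rect]]
    bbox: Rect                      # the meshed domain bounding box
    port: tuple[float, float]       # (r0, r1) annulus on the z = bbox.z0 face
    top_tag: BoundaryTag = BoundaryTag.OUTER_ABSORBING
    side_tag: BoundaryTag = BoundaryTag.OUTER_ABSORBING
    bottom_tag: BoundaryTag = BoundaryTag.OUTER_ABSORBING
    inner_side_tag: BoundaryTag = BoundaryTag.AXIS  # r = bbox.r0 face
    concept: ProbeConcept | None = None
    dims: ProbeDimensions | None = None
    domain: DomainSpec | None = None

    _TOL = 1e-12

    # -- classification ----------------------------------------------------
    def classify(self, r: float, z: float) -> str | None:
        """Region name at a point, or None inside a conductor hole.

        Points outside the bounding box raise; callers sample cell centres
        so boundary coincidence is not an issue.
        """
        for name, rects in self.conductor_rects.items():
            for rect in rects:
                if rect.contains(r, z):
                    return None
        for name, rects in self.region_rects.items():
            for rect in rects:
                if rect.contains(r, z):
                    return name
        raise GeometryError(f"point ({r}, {z}) not covered by any region")

    def edge_tag(self, rm: float, zm: float, tol: float = 1e-9) -> BoundaryTag:
        """Tag for an exterior mesh edge with midpoint (rm, zm)."""
        b = self.bbox
        if zm < b.z0 + tol:
            if self.port[0] - tol < rm < self.port[1] + tol:
                return BoundaryTag.PORT
            return self.top_tag
        if zm > b.z1 - tol:
            return self.bottom_tag
        if rm > b.r1 - tol:
            return self.side_tag
        if rm < b.r0 + tol:
            return self.inner_side_tag
        return BoundaryTag.PEC  # interior exterior-edge: conductor surface

    # -- derived quantities -------------------------------------------------
    def em_area(self) -> float:
        """Half-plane (r, z) area of the meshed EM domain."""
        return sum(rc.area for rects in self.region_rects.values() for rc in rects)

    def mandatory_r_lines(self) -> list[float]:
        vals = {self.bbox.r0, self.bbox.r1}
        for rects in (*self.region_rects.values(), *self.conductor_rects.values()):
            for rc in rects:
                vals.update((rc.r0, rc.r1))
        return sorted(vals)

    def mandatory_z_lines(self) -> list[float]:
        vals = {self.bbox.z0, self.bbox.z1}
        for rects in (*self.region_rects.values(), *self.conductor_rects.values()):
            for rc in rects:
                vals.update((rc.z0, rc.z1))
        return sorted(vals)

    def slot_z_intervals(self) -> list[tuple[float, float]]:
        """Axial extents of outer-conductor slots (refinement plateaus)."""
        out = []
        if self.dims is None:
            return out
        for rc in self.region_rects.get("slot_fill", []):
            # the monopole's bare terminal section is not a slot
            if rc.z1 - rc.z0 <= 2.0 * self.dims.slot_width + 1e-12:
                out.append((rc.z0, rc.z1))
        return out

    def feature_z(self) -> list[float]:
        """Axial locations of strong field gradients (slots, tip, sleeve ends)."""
        feats: set[float] = set()
        for name, rects in self.region_rects.items():
            if name in ("slot_fill", "sleeve_gap_fill"):
                for rc in rects:
                    feats.update((rc.z0, rc.z1))
        for name, rects in self.conductor_rects.items():
            if name in ("tip_cap", "sleeve"):
                for rc in rects:
                    feats.update((rc.z0, rc.z1))
        if self.dims is not None and self.domain is not None:
            feats.add(self.domain.tip_z(self.dims))
        if not feats:  # analytic fixtures: refine nothing special
            feats.add(self.bbox.z1)
        return sorted(feats)

    def probe_radius(self) -> float:
        """Outer radius of the probe band (catheter), 0 for probe-free fixtures."""
        if self.dims is not None:
            return self.dims.r_catheter
        return 0.0

    # -- polygon views -------------------------------------------------------
    def regions(self) -> dict[str, list[list[tuple[float, float]]]]:
        """Region name -> list of closed simple polygons (merged rectangles)."""
        import shapely.geometry as sg
        from shapely.ops import unary_union

        out: dict[str, list[list[tuple[float, float]]]] = {}
        for name, rects in self.region_rects.items():
            merged = unary_union([sg.box(rc.r0, rc.z0, rc.r1, rc.z1) for rc in rects])
            polys = [merged] if merged.geom_type == "Polygon" else list(merged.geoms)
            out[name] = [list(p.exterior.coords) for p in polys]
        return out

    def describe(self) -> str:
        """Plain structured-text dump (region name -> vertex list) for debugging."""
        lines = []
        for name, polys in self.regions().items():
            lines.append(f"region {name}")
            for poly in polys:
                pts = " ".join(f"({r:.6g},{z:.6g})" for r, z in poly)
                lines.append(f"  polygon {pts}")
        for name, rects in self.conductor_rects.items():
            lines.append(f"conductor {name}")
            for rc in rects:
                pts = " ".join(f"({r:.6g},{z:.6g})" for r, z in rc.polygon())
                lines.append(f"  polygon {pts}")
        lines.append(f"port r=[{self.port[0]:.6g},{self.port[1]:.6g}] at z={self.bbox.z0:.6g}")
        return "\n".join(lines)


def default_dimensions(concept: "ProbeConcept | str") -> ProbeDimensions:
    """The common coax/catheter dimensions plus the documented concept defaults."""
    ProbeConcept.parse(concept)
    return ProbeDimensions()


def _split_interval(z0: float, z1: float, gaps: list[tuple[float, float]]) -> list[Rect | None]:
    """Helper: axial segments of [z0, z1] minus the listed (lo, hi) gaps."""
    gaps = sorted(gaps)
    segs = []
    cur = z0
    for lo, hi in gaps:
        if lo > cur:
            segs.append((cur, lo))
        cur = max(cur, hi)
    if cur < z1:
        segs.append((cur, z1))
    return segs


def build_probe_geometry(concept: "ProbeConcept | str",
                         dims: ProbeDimensions | None = None,
                         domain: DomainSpec | None = None) -> GeometryModel:
    """Construct the tagged (r, z) geometry of a probe embedded in tissue.

    Raises :class:`GeometryError` for overlapping features (e.g. dual slots
    overlapping, sleeve colliding with the slot) or a probe that does not
    fit the tissue cylinder.
    """
    concept = ProbeConcept.parse(concept)
    dims = dims or default_dimensions(concept)
    domain = domain or DomainSpec()
    dims.validate(concept)
    domain.validate(dims)

    R, H = domain.tissue_radius, domain.tissue_height
    tip = domain.tip_z(dims)
    ri, rd, ro, rc = dims.r_inner, dims.r_dielectric, dims.r_outer, dims.r_catheter

    regions: dict[str, list[Rect]] = {}
    conductors: dict[str, list[Rect]] = {}

    slotted = concept in (ProbeConcept.SINGLE_SLOT, ProbeConcept.DUAL_SLOT,
                          ProbeConcept.SLEEVE_SINGLE_SLOT)
    cap_top = tip - dims.tip_cap_thickness if slotted else tip

    # coax core
    conductors["inner_conductor"] = [Rect(0.0, ri, 0.0, cap_top)]
    regions["coax_dielectric"] = [Rect(ri, rd, 0.0, cap_top)]
    if slotted:
        conductors["tip_cap"] = [Rect(0.0, ro, cap_top, tip)]

    # outer conductor layer [rd, ro] with gaps
    gaps: list[tuple[float, float]] = []
    if slotted:
        centres = [tip - dims.slot_tip_offset]
        if concept is ProbeConcept.DUAL_SLOT:
            centres.append(tip - dims.slot_tip_offset - dims.slot_separation)
        for zc in centres:
            gaps.append((zc - dims.slot_width / 2, zc + dims.slot_width / 2))
        outer_extent = cap_top
    else:  # monopole: terminal section removed
        gaps.append((tip - dims.monopole_exposed_length, tip))
        outer_extent = tip
    conductors["outer_conductor"] = [Rect(rd, ro, a, b)
                                     for a, b in _split_interval(0.0, outer_extent, gaps)]
    regions["slot_fill"] = [Rect(rd, ro, lo, hi) for lo, hi in sorted(gaps)]

    # catheter (with sleeve carve-out for SSS)
    if concept is ProbeConcept.SLEEVE_SINGLE_SLOT:
        zc_slot = tip - dims.slot_tip_offset
        sl_hi = zc_slot - dims.sleeve_start_offset          # sleeve lower (distal) end
        sl_lo = sl_hi - dims.sleeve_length                  # sleeve upper end
        if sl_lo < 0:
            raise GeometryError("sleeve extends above the probe input plane")
        rs0 = ro + dims.sleeve_gap
        rs1 = rs0 + dims.sleeve_thickness
        conductors["sleeve"] = [Rect(rs0, rs1, sl_lo, sl_hi)]
        regions["sleeve_gap_fill"] = [Rect(ro, rs0, sl_lo, sl_hi)]
        regions["catheter"] = [Rect(ro, rc, 0.0, sl_lo),
                               Rect(rs1, rc, sl_lo, sl_hi),
                               Rect(ro, rc, sl_hi, tip)]
    else:
        regions["catheter"] = [Rect(ro, rc, 0.0, tip)]

    regions["tissue"] = [Rect(rc, R, 0.0, tip), Rect(0.0, R, tip, H)]

    # overlap audit: all rectangles must tile the cylinder section disjointly
    all_rects = [(n, rc_) for n, lst in {**regions, **conductors}.items() for rc_ in lst]
    total = sum(rc_.area for _, rc_ in all_rects)
    if abs(total - R * H) > 1e-12 * R * H * len(all_rects):
        for i in range(len(all_rects)):
            for j in range(i + 1, len(all_rects)):
                a, b = all_rects[i][1], all_rects[j][1]
                if a.r0 < b.r1 and b.r0 < a.r1 and a.z0 < b.z1 and b.z0 < a.z1:
                    raise GeometryError(
                        f"overlapping features: {all_rects[i][0]} and {all_rects[j][0]}")
        raise GeometryError("region rectangles do not tile the domain")

    return GeometryModel(
        region_rects=regions,
        conductor_rects=conductors,
        bbox=Rect(0.0, R, 0.0, H),
        port=(ri, rd),
        concept=concept,
        dims=dims,
        domain=domain,
    )
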