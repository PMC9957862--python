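# Methods

`mwablate` simulates microwave ablation (MWA) of liver tissue by an
interstitial coaxial antenna: a frequency-domain electromagnetic (EM) solve
coupled weakly to a transient bioheat solve on a shared axisymmetric
finite-element mesh, with tissue dielectric properties that fall as the
tissue heats.  This note records the model, its assumptions, the numerical
choices, and what the defaults do and do not represent.

## Physical model

**Electromagnetics.**  The antenna is driven at a single frequency
(2.45 GHz by default) through its coaxial feed.  Only the coaxial TEM mode
is excited, so the field is transverse magnetic about the probe axis:
`E = (E_r, E_z)`, `H = H_phi`.  Time-harmonic Maxwell equations with
constitutive relations reduce to the curl-curl wave equation with complex
permittivity `eps_c = eps_r - j sigma/(omega eps0)` and `mu_r = 1`
(biological tissue is non-magnetic); tissue is source- and charge-free.
Conductor surfaces (inner/outer conductor, sleeve, tip plug) are perfect
electric conductors.  The coax input annulus carries a waveguide-port
condition that injects the incident TEM wave with amplitude
`A0 = sqrt(P Z / (pi ln(r_o/r_i)))` (from the Poynting flux of the mode at
input power `P` and line impedance `Z`) while absorbing the reflected wave;
the incident profile is `A0/r` with uniform phase across the port plane.
The outer tissue boundary carries a first-order absorbing condition using
the local, temperature-dependent tissue impedance, converting the open
problem to a finite domain.

The reflection coefficient is the port projection
`Gamma = int (E - E_inc).E_inc* r dr / int |E_inc|^2 r dr`, the r-weighted
(axisymmetric) annular integral, which coincides with the modal TEM
reflection coefficient; `S11 = 20 log10 |Gamma|`, floored at -160 dB when
`|Gamma| < 1e-8`.  The heat source is the resistive (dipole-rotation) loss
`Qs = sigma |E|^2 / 2` per element.

**Bioheat.**  Temperature obeys `rho C dT/dt = div(k_l grad T) + Qs` on the
tissue region only, with zero flux on every thermal boundary (tissue
exterior and the catheter/tissue interface).  Blood perfusion, metabolic
heat, vaporisation and tissue shrinkage are deliberately absent; the model
is a conduction + EM-source balance.  Consequences worth knowing:
temperatures near the slot can exceed physical limits (no latent-heat
sink), and the minimum tissue temperature can never fall below the initial
37 degC.  Note that *pointwise* temperature is not monotone in time — a
localized hot spike relaxes by conduction — so only the minimum-principle
bound is asserted, not pointwise monotonicity.

**Temperature-dependent dielectric.**  Liver permittivity and conductivity
follow sigmoids of temperature (bovine liver regression at 2.45 GHz):

    eps_r(T) = a3 (1 - 1/(1 + exp(a1 (a2 - T)))) + 1
    sigma(T) = b3 (1 - 1/(1 + exp(b1 (b2 - T))))

with defaults a1 = 0.0764 /degC, a2 = 82.271 degC, a3 = 48.391,
b1 = 0.0697 /degC, b2 = 85.375 degC, b3 = 2.173 S/m, giving
eps_r(37) = 47.9 and sigma(37) = 2.10 S/m.  Both fall strictly with
temperature toward 1 and 0 (desiccated tissue is nearly transparent), which
is the mechanism behind every transient effect the package reports.  The
coefficients are configuration values and are echoed into the run manifest.
Probe materials are static: PTFE coax dielectric and slot fill
(eps_r = 2.03), polymer catheter (eps_r = 2.6), all lossless.  Thermal
constants: rho = 1060 kg/m^3, C = 3600 J/(kg degC), k_l = 0.512 W/(m degC),
temperature-independent.

**Coupling.**  Weak (staggered) coupling: at t = 0 the EM problem is solved
with 37 degC properties and recorded; each step then (i) takes Qs from the
current EM solution, (ii) advances T by one backward-Euler step of length
dt, (iii) re-evaluates tissue properties at the new element temperatures
(or keeps the 37 degC values in `constant` mode), and (iv) re-solves the EM
problem and records.  No inner iteration is performed; none is warranted at
dt = 5 s where the property update is the dominant coupling error.

## Probe concepts and geometry

Four concepts share the common coax/catheter radii 0.135 / 0.335 / 0.46 /
0.895 mm, 1 mm slot width, 0.15 mm sleeve thickness and 70 mm probe length,
fully inserted into an 80 mm high, 40 mm radius tissue cylinder (tip 10 mm
above the far face, port on the entry face):

* **SS** — one slot in the outer conductor, centre 5 mm from the tip.
* **DS** — two slots, centres 8 mm apart.
* **M** — outer conductor removed over the terminal 10 mm (bare
  dielectric-coated monopole).
* **SSS** — SS plus a floating conducting sleeve inside the catheter
  (0.1 mm radial gap off the outer conductor), 15 mm long, starting 10 mm
  proximal of the slot centre.

The slotted concepts carry a 0.5 mm conducting plug joining inner and outer
conductor at the tip (the standard short-circuited termination of coaxial
slot MWA antennas); the monopole tip is open.  Slot gaps are filled with
the coax dielectric material.  The concept-specific offsets are documented,
configurable defaults typical of the MWA antenna literature; computed S11
is sensitive to them at the few-dB level (and the quantities derived from
delivered power inherit that sensitivity), so they are first-class
configuration, not constants.

All regions are axis-aligned rectangles in the (r, z) half-plane, which the
geometry module exploits: regions and conductor holes are rectangle sets,
polygon views are derived, and every interface coordinate is exact.

## Discretisation

**Scalar dual EM formulation.**  Rather than curl-conforming elements for
the meridian E field, the solver discretises the mathematically equivalent
scalar problem for the azimuthal magnetic field, in the scaled unknown
`w = r H_phi` with quadratic Lagrange elements.  Three properties motivate
this: (1) the coaxial TEM mode is `w = const`, exactly representable, so
the thin, strongly curved coax layers are accurate on coarse radial meshes
(in the unscaled H_phi variable the same meshes show O(1) spurious
reflection); (2) PEC surfaces become natural (do-nothing) boundaries; (3)
the port and absorbing conditions are scalar Robin terms
`j k0 / sqrt(eps_c)` on the boundary mass, with the port load
`2 j k0/sqrt(eps_d) w_inc`, `w_inc = A0/Z`.  E is recovered per element as
`E_r = -(dw/dz)/(j omega eps0 eps_c r)`, `E_z = (dw/dr)/(j omega eps0 eps_c r)`.
The axis carries `w = 0`.  The discrete system is complex symmetric and is
solved by sparse LU with deterministic ordering.  The bioheat equation uses
quadratic Lagrange elements on the tissue subdomain with the r-weighted
measure; the constant implicit operator is factorised once per run.

The governing verification contract is analytic, not comparative: a
matched straight coax must transmit (|Gamma| <= 0.05, field within 2% of
A0/r), a shorted lossless coax must reflect (|Gamma| = 1 +- 1%), and
(1 - |Gamma|^2) P must equal the revolved volume integral of Qs within 5%
on lossy problems.  The shipped solver passes these at ~1e-4, <0.5%, and
~2% respectively; S11 of the probe models is mesh-converged to <0.01 dB
across successive refinements.

**Meshing.**  All interfaces are rectilinear, so the mesh is a graded
tensor product of r- and z-lines containing every interface exactly; cells
are classified by centre and split into two triangles.  Line density
follows the inverse CDF of a 1/size field: h_fine (default 0.1 mm) within a
2 mm plateau of any slot, growing linearly (grading 0.35 per unit distance)
toward h_far (default 2 mm), additionally capped by the in-tissue
wavelength over `wavelength_points` (default 10; lambda ~ 17.5 mm at
37 degC) and kept fine near the port plane for an accurate port integral.
Each coax layer gets at least two radial cells.  The mesh is deterministic
by construction (pure arithmetic, no randomised point insertion).  Cells
far from the refinement zones are anisotropic (fine across thin layers,
coarse along them); this anisotropy is aligned with the field anisotropy
and is benign for the nodal discretisation — triangle quality (min angle
>= 30 deg) is guaranteed only inside the isotropic near-slot zone, and
accuracy is governed by the analytic oracles and refinement checks above
rather than by a global angle bound.

## Shape analysis

A thresholded field region {field >= threshold} in the tissue is measured
on the mirrored full cross-section (x in [-R, R]): the field is sampled on
a uniform raster (default 0.2 mm; guarded at 10 um), non-tissue points and
the probe band are forced far below threshold so isolines close along the
catheter surface and domain edges, the threshold isoline is traced by
marching squares with linear interpolation, mirrored about the axis, and
assembled into polygons with holes by containment parity.  Area and
perimeter aggregate all disjoint components and hole rims;
circularity = 4 pi A / P^2 (1 for a circle; scale-invariant).  Metrics are
reported for the mirrored cross-section, matching the ~1e-4 m^2 scale of
the reference areas; the half-plane area is also exposed.  SAR shapes use
the per-element Qs field at 1 kW/m^3 by default; temperature shapes use the
quadratic nodal field at 50 degC.  An empty region (threshold above the
maximum) yields area 0 and undefined (NaN) circularity, not an error.

One caution from the study defaults: at 30 W in liver, attenuation
(~56 Np/m) places the 1 kW/m^3 loss-density isocontour at 30-40 mm from the
probe, so the t = 0 SAR shape is clipped by the tissue boundary and its
area (~56e-4 m^2 mirrored) mostly measures the domain, not the antenna; a
threshold three orders of magnitude higher (e.g. the 1 kW/kg mass-specific
level, ~1.06e6 W/m^3) produces compact antenna-shaped contours.  The
threshold is a plain configuration value (`run.sar_threshold`) for exactly
this reason.

## Defaults, determinism and problem sizes

The default configuration is the comparative study setup: 2.45 GHz, 30 W,
300 s at dt = 5 s (61 records), SAR threshold 1 kW/m^3, temperature
threshold 50 degC, dynamic properties, raster 0.2 mm.  Default meshes run
15k-48k P2 unknowns per probe (monopole smallest, dual-slot largest),
chosen so a full 300 s coupled run of one probe completes in one to three
minutes on a single core while S11 and the shape metrics are converged at
the tolerances above; halving the mesh controls reproduces S11 to better
than 0.01 dB.  Every stage is deterministic: identical configurations
reproduce time series bit-for-bit, and the run manifest written beside each
time series is sufficient to reproduce the run.

## Known limitations

* No perfusion, metabolism, vaporisation, or damage integrals; near-slot
  temperatures are physical only in the conduction-model sense.
* First-order absorbing boundary (no PML); residual boundary reflection is
  part of the ~2-5% power-balance slack.
* The dielectric sigmoid is a bovine-liver regression; no dispersion across
  frequency and no tissue heterogeneity.
* Concept-specific probe offsets are literature-typical defaults; S11 and
  the shape metrics derived from delivered power vary by several dB /
  tens of percent across their plausible ranges.
* The weak-coupling loop with dt = 5 s can limit-cycle when near-slot
  elements cross the sigmoid transition within one step; the 50 degC
  contour metrics are robust to this, the instantaneous S11 trace less so.
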