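"""Tissue and probe material models.

Liver dielectric properties fall with temperature as bound water is driven
out; both the relative permittivity and the effective conductivity follow a
sigmoid of temperature fitted to bovine liver measurements at 2.45 GHz
(Ji & Brace regression).  The probe materials (PTFE coax dielectric,
polymer catheter) are static and lossless; magnetic permeability is that of
free space everywhere.

The shipped sigmoid coefficients are configurable defaults — the run
manifest always echoes the coefficient set actually used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SigmoidCoefficients",
    "StaticMaterial",
    "ThermalProperties",
    "MaterialAssignment",
    "LIVER_SIGMOID",
    "LIVER_THERMAL",
    "permittivity_at_temperature",
    "conductivity_at_temperature",
    "material_field",
    "default_assignment",
]

# saturate the sigmoid argument; exp(±60) is far beyond any physical range
_EXP_CLIP = 60.0


@dataclass(frozen=True)
class SigmoidCoefficients:
    """Coefficients of the sigmoidal temperature dependence.

    eps_r(T) = alpha3 * (1 - 1 / (1 + exp(alpha1 (alpha2 - T)))) + 1
    sigma(T) = beta3  * (1 - 1 / (1 + exp(beta1  (beta2  - T))))

    alpha1, beta1: 1/degC (transition sharpness); alpha2, beta2: degC
    (transition midpoints); alpha3: permittivity span; beta3: S/m span.
    """

    alpha1: float = 0.0764
    alpha2: float = 82.271
    alpha3: float = 48.391
    beta1: float = 0.0697
    beta2: float = 85.375
    beta3: float = 2.173

    def __post_init__(self):
        if self.alpha1 <= 0 or self.beta1 <= 0:
            raise ValueError("sigmoid slopes alpha1, beta1 must be positive")
        if self.alpha3 <= 0 or self.beta3 <= 0:
            raise ValueError("property spans alpha3, beta3 must be positive")

    def permittivity(self, T):
        return permittivity_at_temperature(T, self)

    def conductivity(self, T):
        return conductivity_at_temperature(T, self)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(np.clip(x, -_EXP_CLIP, _EXP_CLIP)))


def permittivity_at_temperature(T, c: SigmoidCoefficients):
    """Relative permittivity of liver at temperature T (degC).

    Strictly decreasing in T, with limits alpha3 + 1 (cold) and 1 (hot).
    """
    return c.alpha3 * (1.0 - _sigmoid(c.alpha1 * (c.alpha2 - np.asarray(T, float)))) + 1.0


def conductivity_at_temperature(T, c: SigmoidCoefficients):
    """Effective conductivity (S/m) of liver at temperature T (degC)."""
    return c.beta3 * (1.0 - _sigmoid(c.beta1 * (c.beta2 - np.asarray(T, float))))


@dataclass(frozen=True)
class StaticMaterial:
    eps_r: float
    sigma: float = 0.0
    mu_r: float = 1.0

    def __post_init__(self):
        if self.eps_r < 1.0 or self.sigma < 0.0:
            raise ValueError("require eps_r >= 1 and sigma >= 0")
        if self.mu_r != 1.0:
            raise ValueError("non-magnetic media only (mu_r = 1)")


@dataclass(frozen=True)
class ThermalProperties:
    """Constant thermal coefficients of liver tissue."""

    rho: float = 1060.0   # kg/m^3
    C: float = 3600.0     # J/(kg degC)
    k_l: float = 0.512    # W/(m degC)

    def __post_init__(self):
        if min(self.rho, self.C, self.k_l) <= 0:
            raise ValueError("thermal properties must be positive")


LIVER_SIGMOID = SigmoidCoefficients()
LIVER_THERMAL = ThermalProperties()

PTFE = StaticMaterial(eps_r=2.03, sigma=0.0)
CATHETER = StaticMaterial(eps_r=2.6, sigma=0.0)


@dataclass
class MaterialAssignment:
    """Per-region material map with one temperature-dependent tissue region."""

    static: dict[str, StaticMaterial] = field(default_factory=lambda: {
        "coax_dielectric": PTFE,
        "slot_fill": PTFE,
        "catheter": CATHETER,
        "sleeve_gap_fill": CATHETER,
    })
    tissue_region: str = "tissue"
    sigmoid: SigmoidCoefficients = LIVER_SIGMOID
    thermal: ThermalProperties = LIVER_THERMAL
    property_mode: str = "dynamic"   # or "constant" (frozen at 37 degC)
    reference_temperature: float = 37.0

    def __post_init__(self):
        if self.property_mode not in ("dynamic", "constant"):
            raise ValueError("property_mode must be 'dynamic' or 'constant'")
        if self.tissue_region in self.static:
            raise ValueError("tissue region cannot also carry a static material")


def default_assignment(property_mode: str = "dynamic") -> MaterialAssignment:
    return MaterialAssignment(property_mode=property_mode)


def material_field(mesh, T_vertices: np.ndarray, assignment: MaterialAssignment):
    """Per-element (eps_r, sigma) over the mesh at vertex temperatures T.

    Tissue elements evaluate the sigmoid at the element temperature (mean of
    corner vertex temperatures); other regions take their static values.  In
    constant mode the tissue values are frozen at the reference temperature.
    """
    T_vertices = np.asarray(T_vertices, float)
    if T_vertices.shape[0] != mesh.n_vertices:
        raise ValueError(
            f"temperature field has {T_vertices.shape[0]} entries for "
            f"{mesh.n_vertices} mesh vertices")

    eps = np.empty(mesh.n_triangles)
    sig = np.empty(mesh.n_triangles)
    for i, name in enumerate(mesh.region_names):
        sel = mesh.region_id == i
        if not np.any(sel):
            continue
        if name == assignment.tissue_region:
            if assignment.property_mode == "constant":
                T_el = np.full(sel.sum(), assignment.reference_temperature)
            else:
                T_el = T_vertices[mesh.triangles[sel]].mean(axis=1)
            eps[sel] = assignment.sigmoid.permittivity(T_el)
            sig[sel] = assignment.sigmoid.conductivity(T_el)
        else:
            mat = assignment.static.get(name)
            if mat is None:
                raise ValueError(f"no material assigned to region {name!r}")
            eps[sel] = mat.eps_r
            sig[sel] = mat.sigma
    return eps, sig
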