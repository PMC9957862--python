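"""Axisymmetric frequency-domain electromagnetic solver.

The probe excites only the coaxial TEM mode, so the time-harmonic field is
transverse magnetic with respect to the axis: E = (E_r, E_z), H = H_phi.
The curl-curl problem for the meridian electric field is solved through its
scalar dual, the azimuthal magnetic field u = H_phi:

    curl( eps_c^-1 curl(u phi_hat) ) - k0^2 u phi_hat = 0,
    eps_c = eps_r - j sigma / (omega eps0),

discretised with quadratic nodal elements in the scaled unknown
w = r H_phi, for which the coaxial TEM mode is exactly constant across the
annulus (essential for accuracy in the thin, strongly curved coax layers).
The two formulations are equivalent for this mode family; the scalar one
keeps conductor surfaces as natural (do-nothing) boundaries and makes the
TEM port condition a simple Robin term.  E is recovered per element from
E = curl(H) / (j omega eps0 eps_c):
E_r = -(dw/dz) / (j omega eps0 eps_c r), E_z = (dw/dr) / (j omega eps0 eps_c r).

Boundary conditions:

* Waveguide port (coax input annulus): Robin condition
  du/dn + gamma_d u = 2 gamma_d u_inc with u_inc = A0 / (Z r), which
  injects the incident TEM wave and absorbs the reflected one.
* First-order absorbing condition on the outer tissue boundary, using the
  local (temperature-dependent) tissue impedance.
* Perfect electric conductor on all metal surfaces: natural.
* Axis r = 0: H_phi = 0 (essential).

Sign conventions follow the e^{+j omega t} time dependence, so passive
media have Im(eps_c) <= 0 and outgoing waves vary as e^{-j k z}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

from . import _fem
from .geometry import BoundaryTag
from .mesh import TriangleMesh

__all__ = ["SourceSpec", "EMSolution", "EMSolverError", "incident_amplitude",
           "incident_field", "solve_em", "compute_loss_density",
           "reflection_coefficient", "S11_FLOOR_DB"]

EPS0 = 8.8541878128e-12
MU0 = 4e-7 * np.pi
C0 = 299_792_458.0
Z0 = np.sqrt(MU0 / EPS0)

S11_FLOOR_DB = -160.0


class EMSolverError(RuntimeError):
    pass


def incident_amplitude(power: float, Z: float, r_i: float, r_o: float) -> float:
    """Peak TEM field amplitude A0 (V) from input power and coax geometry.

    A0 = sqrt( P Z / (pi ln(r_o / r_i)) ); the incident radial field is
    A0 / r across the annulus.
    """
    if r_o <= r_i or r_i <= 0:
        raise ValueError("require 0 < r_i < r_o")
    if Z <= 0:
        raise ValueError("wave impedance must be positive")
    if power < 0:
        raise ValueError("power must be nonnegative")
    return float(np.sqrt(power * Z / (np.pi * np.log(r_o / r_i))))


@dataclass
class SourceSpec:
    """Coaxial TEM port excitation at a fixed frequency."""

    frequency: float = 2.45e9
    power: float = 30.0
    r_i: float = 0.135e-3
    r_o: float = 0.335e-3
    eps_dielectric: float = 2.03

    def __post_init__(self):
        if self.r_o <= self.r_i:
            raise ValueError("port annulus requires r_i < r_o")

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.frequency

    @property
    def k0(self) -> float:
        return self.omega / C0

    @property
    def Z(self) -> float:
        """Wave impedance of the coax dielectric (Ohm)."""
        return Z0 / np.sqrt(self.eps_dielectric)

    @property
    def A0(self) -> float:
        return incident_amplitude(self.power, self.Z, self.r_i, self.r_o)

    @property
    def gamma0_port(self) -> complex:
        return 1j * self.k0 * np.sqrt(self.eps_dielectric)

    def gamma0_tissue(self, eps_c: complex) -> complex:
        return 1j * self.k0 * np.sqrt(eps_c)


def incident_field(source: SourceSpec, r) -> np.ndarray:
    """Incident radial TEM field A0 / r on the port annulus (uniform phase)."""
    r = np.asarray(r, float)
    if np.any((r < source.r_i - 1e-12) | (r > source.r_o + 1e-12)):
        raise ValueError("radius outside the port annulus")
    return (source.A0 / r).astype(complex)


def reflection_coefficient(E_port, E_inc, r, weights):
    """Port-projection reflection coefficient from sampled radial fields.

    Gamma = int (E - E_inc) E_inc* r dr / int |E_inc|^2 r dr over the port
    annulus (axisymmetric r-weighted line integral), with
    s11_db = 20 log10 |Gamma| floored at S11_FLOOR_DB.
    """
    E_port = np.asarray(E_port, complex).ravel()
    E_inc = np.asarray(E_inc, complex).ravel()
    r = np.asarray(r, float).ravel()
    w = np.asarray(weights, float).ravel()
    denom = np.sum(w * r * (E_inc * np.conj(E_inc)))
    if abs(denom) == 0.0:
        raise ValueError("zero incident energy on the port")
    gamma = complex(np.sum(w * r * (E_port - E_inc) * np.conj(E_inc)) / denom)
    mag = abs(gamma)
    s11_db = S11_FLOOR_DB if mag < 1e-8 else float(20 * np.log10(mag))
    return gamma, max(s11_db, S11_FLOOR_DB)


def compute_loss_density(E_sq, sigma) -> np.ndarray:
    """Resistive (dipole-rotation) loss density Qs = sigma |E|^2 / 2, W/m^3."""
    return 0.5 * np.asarray(sigma, float) * np.asarray(E_sq, float)


@dataclass
class EMSolution:
    """One frequency-domain solve: H_phi dofs, derived loss and port scalars."""

    mesh: TriangleMesh
    space: object
    w: np.ndarray                 # complex scaled field r * H_phi at P2 dofs
    eps_c: np.ndarray             # per-element complex permittivity used
    sigma: np.ndarray             # per-element conductivity used
    source: SourceSpec
    Qs: np.ndarray                # per-element loss density, W/m^3
    E_sq: np.ndarray              # per-element mean |E|^2, (V/m)^2
    E_elem: np.ndarray            # per-element mean complex (E_r, E_z)
    Gamma: complex
    s11_db: float
    power_absorbed: float         # 2 pi int Qs r dr dz over the whole domain
    warnings: list = field(default_factory=list)

    @property
    def delivered_power(self) -> float:
        return (1.0 - abs(self.Gamma) ** 2) * self.source.power


def _complex_permittivity(eps_r, sigma, omega):
    return np.asarray(eps_r, float) - 1j * np.asarray(sigma, float) / (omega * EPS0)


def solve_em(mesh: TriangleMesh, props, source: SourceSpec,
             space=None) -> EMSolution:
    """Solve the axisymmetric wave problem for one material state.

    ``props`` is the per-element (eps_r, sigma) pair from
    :func:`mwablate.materials.material_field`.
    """
    eps_r, sigma = props
    eps_r = np.asarray(eps_r, float)
    sigma = np.asarray(sigma, float)
    if eps_r.shape[0] != mesh.n_triangles:
        raise ValueError("property arrays do not match the mesh")
    if space is None:
        space = _fem.build_space(mesh)

    omega, k0 = source.omega, source.k0
    eps_c = _complex_permittivity(eps_r, sigma, omega)

    A = _fem.assemble_form(mesh, space, "curl_w", 1.0 / eps_c, -k0 ** 2 + 0j)

    # Robin terms: j k0 / sqrt(eps_c) weighting on port and absorbing edges
    port_edges = mesh.tag_edges(BoundaryTag.PORT)
    abc_edges = mesh.tag_edges(BoundaryTag.OUTER_ABSORBING)
    if len(port_edges) == 0:
        raise EMSolverError("mesh carries no port edges")
    sqrt_ed = np.sqrt(complex(source.eps_dielectric, 0.0))
    A = A + _fem.assemble_edge_mass(mesh, space, port_edges, 1j * k0 / sqrt_ed,
                                    measure="inv_r")
    if len(abc_edges) > 0:
        eps_loc = eps_c[mesh.boundary_elem[abc_edges]]
        A = A + _fem.assemble_edge_mass(mesh, space, abc_edges,
                                        1j * k0 / np.sqrt(eps_loc),
                                        measure="inv_r")

    # incident w = r H_phi = A0 / Z, constant across the port annulus
    w_inc = source.A0 / source.Z
    b = _fem.assemble_edge_load(mesh, space, port_edges, lambda r: w_inc + 0 * r,
                                coeff=2j * k0 / sqrt_ed, measure="inv_r")

    axis_edges = mesh.tag_edges(BoundaryTag.AXIS)
    if len(axis_edges) > 0:
        axis_dofs = np.unique(space.boundary_edge_dofs(axis_edges).ravel())
        A, b = _fem.apply_dirichlet(A, b, axis_dofs, 0.0)

    warns = []
    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:  # zero input power: trivial field, no port projection
        w = np.zeros(space.n_dofs, complex)
        resid = 0.0
    else:
        lu = spla.splu(A.tocsc())
        w = lu.solve(b)
        resid = np.linalg.norm(A @ w - b) / bnorm
    if resid > 1e-8:
        raise EMSolverError(f"linear solve residual {resid:.2e} exceeds 1e-8; "
                            "system likely ill-conditioned")

    # --- derived fields ---------------------------------------------------
    all_elems = np.arange(mesh.n_triangles)
    _, dw_dr, dw_dz, r_q, w_q = _fem.eval_field_and_gradient(mesh, space, w, all_elems)
    jwe = 1j * omega * EPS0 * eps_c[:, None]
    Er_q = -dw_dz / (jwe * r_q)
    Ez_q = dw_dr / (jwe * r_q)
    Esq_q = np.abs(Er_q) ** 2 + np.abs(Ez_q) ** 2
    cellw = w_q.sum(axis=1)
    E_sq = (Esq_q * w_q).sum(axis=1) / cellw
    E_elem = np.stack([(Er_q * w_q).sum(axis=1) / cellw,
                       (Ez_q * w_q).sum(axis=1) / cellw], axis=1)
    Qs = compute_loss_density(E_sq, sigma)
    power_absorbed = _fem.integrate_elementwise(mesh, Qs)

    # --- port reflection (projection on the incident TEM profile) ---------
    if bnorm == 0.0:
        Gamma, s11_db = 0.0 + 0.0j, S11_FLOOR_DB
    else:
        Er_p, r_p, w_p = _port_electric_field(mesh, space, w, eps_c, source,
                                              port_edges)
        E_inc = incident_field(source, np.clip(r_p, source.r_i, source.r_o))
        Gamma, s11_db = reflection_coefficient(Er_p, E_inc, r_p, w_p)
    if abs(Gamma) > 1.0 + 1e-3:
        warns.append(f"nonphysical |Gamma| = {abs(Gamma):.4f} > 1")
        warnings.warn(warns[-1], RuntimeWarning, stacklevel=2)

    return EMSolution(mesh=mesh, space=space, w=w, eps_c=eps_c, sigma=sigma,
                      source=source, Qs=Qs, E_sq=E_sq, E_elem=E_elem,
                      Gamma=Gamma, s11_db=s11_db,
                      power_absorbed=power_absorbed, warnings=warns)


def _port_electric_field(mesh, space, w, eps_c, source, port_edges):
    """Radial E at port-edge quadrature points, with integration weights."""
    from ._fem import _EQ, _EW

    pa = mesh.vertices[mesh.boundary_edges[port_edges, 0]]
    pb = mesh.vertices[mesh.boundary_edges[port_edges, 1]]
    elems = mesh.boundary_elem[port_edges]
    L = np.linalg.norm(pb - pa, axis=1)
    # quadrature points along each edge
    pts = pa[:, None, :] * (1 - _EQ)[None, :, None] + pb[:, None, :] * _EQ[None, :, None]
    k, q = pts.shape[0], pts.shape[1]
    tri = mesh.triangles[elems]
    p0 = mesh.vertices[tri[:, 0]]
    J = np.stack([mesh.vertices[tri[:, 1]] - p0, mesh.vertices[tri[:, 2]] - p0], axis=2)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    d = pts - p0[:, None, :]
    xi = (J[:, 1, 1, None] * d[..., 0] - J[:, 0, 1, None] * d[..., 1]) / detJ[:, None]
    eta = (-J[:, 1, 0, None] * d[..., 0] + J[:, 0, 0, None] * d[..., 1]) / detJ[:, None]
    lam = np.stack([1 - xi - eta, xi, eta], axis=-1).reshape(-1, 3)
    _, dN = _fem._p2_shapes(lam)
    invJT = np.empty_like(J)
    invJT[:, 0, 0] = J[:, 1, 1]
    invJT[:, 0, 1] = -J[:, 1, 0]
    invJT[:, 1, 0] = -J[:, 0, 1]
    invJT[:, 1, 1] = J[:, 0, 0]
    invJT /= detJ[:, None, None]
    dN = dN.reshape(k, q, 6, 2)
    gphys = np.einsum("kab,kqib->kqia", invJT, dN)
    we = np.asarray(w)[space.tri_dofs[elems]]
    dw_dz = np.einsum("kqi,ki->kq", gphys[..., 1], we)
    jwe = 1j * source.omega * EPS0 * eps_c[elems][:, None]
    Er = -dw_dz / (jwe * pts[..., 0])
    r_p = pts[..., 0].ravel()
    w_p = (np.broadcast_to(_EW[None, :], (k, q)) * L[:, None]).ravel()
    return Er.ravel(), r_p, w_p
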