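"""Transient bioheat solver on the tissue region.

Heat conduction with the electromagnetic loss density as source,

    rho C dT/dt = div(k_l grad T) + Qs,    zero flux on all boundaries,

advanced by backward Euler on quadratic Lagrange elements over the tissue
subdomain of the shared mesh (probe interior excluded; the catheter/tissue
interface is insulated).  Blood perfusion and metabolic heat are not
modelled.  The thermal coefficients are constant, so the implicit operator
is factorised once per (mesh, dt) and reused across all steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from . import _fem
from .materials import ThermalProperties

__all__ = ["ThermalState", "BioheatSystem", "step_bioheat", "BioheatError"]


class BioheatError(RuntimeError):
    pass


@dataclass
class ThermalState:
    """Nodal (P2) temperature field on the full mesh at one time, degC.

    Non-tissue dofs stay at the initial temperature and are never updated.
    """

    T: np.ndarray
    time: float = 0.0


class BioheatSystem:
    """Factorised backward-Euler operator for a fixed mesh, dt and properties."""

    def __init__(self, mesh, space, props: ThermalProperties, dt: float,
                 tissue_region: str = "tissue"):
        if dt <= 0:
            raise BioheatError("dt must be positive")
        self.mesh = mesh
        self.space = space
        self.props = props
        self.dt = dt
        self.tissue_elems = np.nonzero(
            mesh.region_id == mesh.region_index(tissue_region))[0]
        self.tissue_dofs = np.unique(space.tri_dofs[self.tissue_elems].ravel())
        self._glob2loc = -np.ones(space.n_dofs, dtype=int)
        self._glob2loc[self.tissue_dofs] = np.arange(len(self.tissue_dofs))

        rhoC = props.rho * props.C
        K = _fem.assemble_form(mesh, space, "grad", props.k_l, 0.0,
                               elems=self.tissue_elems, dtype=float)
        M = _fem.assemble_form(mesh, space, "grad", 0.0, 1.0,
                               elems=self.tissue_elems, dtype=float)
        self.M = M.tocsr()[self.tissue_dofs][:, self.tissue_dofs]
        self.K = K.tocsr()[self.tissue_dofs][:, self.tissue_dofs]
        A = (rhoC / dt) * self.M + self.K
        self._lu = spla.splu(A.tocsc())
        self._rhoC = rhoC

    def load_vector(self, Qs: np.ndarray) -> np.ndarray:
        """Tissue-local load from a per-element loss density (tissue slots)."""
        Qs = np.asarray(Qs, float)
        if Qs.shape[0] == self.mesh.n_triangles:
            Qs = Qs[self.tissue_elems]
        if Qs.shape[0] != len(self.tissue_elems):
            raise BioheatError("Qs length matches neither mesh nor tissue elements")
        if not np.all(np.isfinite(Qs)):
            raise BioheatError("non-finite loss density")
        b = _fem.assemble_element_load(self.mesh, self.space, Qs,
                                       elems=self.tissue_elems)
        return b[self.tissue_dofs]

    def step(self, state: ThermalState, Qs: np.ndarray) -> ThermalState:
        """One backward-Euler step; returns the new state at time + dt."""
        T = np.asarray(state.T, float)
        T_loc = T[self.tissue_dofs]
        rhs = (self._rhoC / self.dt) * (self.M @ T_loc) + self.load_vector(Qs)
        T_new_loc = self._lu.solve(rhs)
        if not np.all(np.isfinite(T_new_loc)):
            raise BioheatError("thermal linear solve produced non-finite values")
        T_new = T.copy()
        T_new[self.tissue_dofs] = T_new_loc
        return ThermalState(T=T_new, time=state.time + self.dt)

    def energy(self, state: ThermalState) -> float:
        """rho C * revolved integral of T over tissue (J per rad/2pi... in J)."""
        return self._rhoC * _fem.integrate_nodal(
            self.mesh, self.space, state.T, elems=self.tissue_elems)


def step_bioheat(state: ThermalState, Qs, dt: float, props: ThermalProperties,
                 *, mesh=None, space=None, system: BioheatSystem | None = None
                 ) -> ThermalState:
    """Functional single-step interface; builds (or reuses) the implicit system.

    Prefer constructing a :class:`BioheatSystem` once when stepping many
    times with the same mesh and dt.
    """
    if system is None:
        if mesh is None:
            raise BioheatError("either a system or a mesh is required")
        if space is None:
            space = _fem.build_space(mesh)
        system = BioheatSystem(mesh, space, props, dt)
    elif system.dt != dt or system.props != props:
        raise BioheatError("system was built with different dt or properties")
    return system.step(state, Qs)
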