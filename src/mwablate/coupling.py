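"""Weakly coupled electromagnetic-thermal ablation loop.

One run alternates a frequency-domain EM solve with a backward-Euler
bioheat step.  The record at t = 0 is the first EM solve with the tissue at
its uniform initial temperature; each subsequent step (i) takes the loss
density of the current EM solution, (ii) advances the temperature by dt,
(iii) re-evaluates the tissue dielectric properties at the new temperature
(dynamic mode) or keeps the 37 degC values (constant mode), and (iv)
re-solves the EM problem and records the observables.  No inner fixed-point
iteration is performed (weak coupling).  The whole loop is deterministic.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np

from . import _fem
from .bioheat import BioheatSystem, ThermalState
from .em import SourceSpec, solve_em
from .geometry import DomainSpec, ProbeConcept, ProbeDimensions, build_probe_geometry
from .materials import MaterialAssignment, default_assignment, material_field
from .mesh import MeshControls, generate_mesh
from .shapes import (ElementFieldSampler, NodalFieldSampler,
                     extract_threshold_shape, shape_metrics)

__all__ = ["SimulationConfig", "TimeSeriesRecord", "SimulationResult",
           "run_simulation", "SimulationError"]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    """Fully resolved configuration of one coupled ablation run."""

    concept: ProbeConcept = ProbeConcept.SINGLE_SLOT
    dims: ProbeDimensions | None = None
    domain: DomainSpec = field(default_factory=DomainSpec)
    mesh: MeshControls = field(default_factory=MeshControls)
    materials: MaterialAssignment = field(default_factory=default_assignment)
    frequency: float = 2.45e9
    power: float = 30.0
    duration: float = 300.0
    dt: float = 5.0
    sar_threshold: float = 1000.0   # W/m^3 isocontour for SAR shapes
    temp_threshold: float = 50.0    # degC isocontour for thermal shapes
    initial_temperature: float = 37.0
    raster: float = 2.0e-4
    store_snapshots: bool = False

    def validate(self) -> None:
        if self.duration < 0 or self.dt <= 0:
            raise SimulationError("require duration >= 0 and dt > 0")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise SimulationError(
                f"duration {self.duration} is not an integer multiple of dt {self.dt}")
        if self.sar_threshold <= 0 or self.temp_threshold <= 0:
            raise SimulationError("isocontour thresholds must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def source(self) -> SourceSpec:
        dims = self.dims or ProbeDimensions()
        eps_d = 2.03
        for name in ("coax_dielectric",):
            if name in self.materials.static:
                eps_d = self.materials.static[name].eps_r
        return SourceSpec(frequency=self.frequency, power=self.power,
                          r_i=dims.r_inner, r_o=dims.r_dielectric,
                          eps_dielectric=eps_d)


@dataclass
class TimeSeriesRecord:
    t: float
    s11_db: float
    sar_area: float          # m^2, mirrored cross-section
    sar_circularity: float   # NaN when the thresholded shape is empty
    temp_area: float
    temp_circularity: float
    T_max: float

    _FIELDS = ("t", "s11_db", "sar_area", "sar_circularity",
               "temp_area", "temp_circularity", "T_max")


@dataclass
class SimulationResult:
    config: SimulationConfig
    records: list
    mesh: object
    space: object
    final_state: ThermalState
    final_em: object
    snapshots: list = field(default_factory=list)
    wall_time: float = 0.0

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame([{k: getattr(r, k) for k in TimeSeriesRecord._FIELDS}
                             for r in self.records])


def _shape_observables(config, geometry, mesh, space, em_sol, state):
    """(sar_area, sar_circ, temp_area, temp_circ) for one record."""
    tissue = np.nonzero(mesh.region_id == mesh.region_index("tissue"))[0]
    sar = ElementFieldSampler(mesh, em_sol.Qs, elems=tissue)
    out = []
    for sampler, thr in ((sar, config.sar_threshold),):
        shp = extract_threshold_shape(sampler, thr, geometry, raster=config.raster)
        out.append(shp)
    temp = NodalFieldSampler(mesh, space, state.T, elems=tissue)
    out.append(extract_threshold_shape(temp, config.temp_threshold, geometry,
                                       raster=config.raster))
    metrics = []
    for shp in out:
        if shp.is_empty:
            metrics.extend([0.0, float("nan")])
        else:
            m = shape_metrics(shp)
            metrics.extend([m.area, m.circularity])
    return tuple(metrics)  # (sar_area, sar_circ, temp_area, temp_circ)


def run_simulation(config: SimulationConfig, progress=None) -> SimulationResult:
    """Run the coupled EM-bioheat loop and return per-step observables.

    ``progress`` is an optional callback (step_index, record) invoked after
    each record; any stage failure is re-raised with the failing step and
    stage name.
    """
    t0 = _time.perf_counter()
    config.validate()
    dims = config.dims or ProbeDimensions()

    stage = "geometry"
    step = 0
    try:
        geometry = build_probe_geometry(config.concept, dims, config.domain)
        stage = "meshing"
        tissue37 = (config.materials.sigmoid.permittivity(config.initial_temperature),
                    config.materials.sigmoid.conductivity(config.initial_temperature))
        mesh = generate_mesh(geometry, config.mesh, frequency=config.frequency,
                             tissue_props_37=tissue37)
        space = _fem.build_space(mesh)
        source = config.source()

        stage = "thermal setup"
        bio = BioheatSystem(mesh, space, config.materials.thermal, config.dt)
        state = ThermalState(T=np.full(space.n_dofs, config.initial_temperature,
                                       float), time=0.0)
        # P2 dof temperatures: vertex slots first; material_field reads vertices
        stage = "em solve"
        props = material_field(mesh, state.T[:mesh.n_vertices], config.materials)
        em_sol = solve_em(mesh, props, source, space=space)

        records = []
        snapshots = []

        def record(state, em_sol):
            sar_area, sar_c, temp_area, temp_c = _shape_observables(
                config, geometry, mesh, space, em_sol, state)
            tissue_dofs = bio.tissue_dofs
            rec = TimeSeriesRecord(
                t=state.time, s11_db=em_sol.s11_db,
                sar_area=sar_area, sar_circularity=sar_c,
                temp_area=temp_area, temp_circularity=temp_c,
                T_max=float(state.T[tissue_dofs].max()))
            records.append(rec)
            if config.store_snapshots:
                snapshots.append({"t": state.time, "Qs": em_sol.Qs.copy(),
                                  "E_mag": np.sqrt(em_sol.E_sq),
                                  "T": state.T.copy(),
                                  "Gamma": em_sol.Gamma})
            if progress is not None:
                progress(len(records) - 1, rec)

        stage = "shape analysis"
        record(state, em_sol)

        for step in range(1, config.n_steps + 1):
            stage = "bioheat step"
            state = bio.step(state, em_sol.Qs)
            stage = "property update"
            props = material_field(mesh, state.T[:mesh.n_vertices], config.materials)
            stage = "em solve"
            em_sol = solve_em(mesh, props, source, space=space)
            stage = "shape analysis"
            record(state, em_sol)
    except Exception as exc:
        raise SimulationError(
            f"simulation failed at step {step}, stage '{stage}': {exc}") from exc

    return SimulationResult(config=config, records=records, mesh=mesh,
                            space=space, final_state=state, final_em=em_sol,
                            snapshots=snapshots,
                            wall_time=_time.perf_counter() - t0)
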