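"""Configuration loading, time-series tables, manifests and field export.

Configuration is YAML with strict key checking; all lengths are metres,
times seconds, temperatures degC, power watts.  The run manifest echoes
every resolved parameter (including the dielectric sigmoid coefficient set)
so a run can be reproduced bit-for-bit from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import time

import numpy as np
import pandas as pd
import yaml

from .coupling import SimulationConfig, TimeSeriesRecord
from .geometry import DomainSpec, ProbeConcept, ProbeDimensions
from .materials import (MaterialAssignment, SigmoidCoefficients, StaticMaterial,
                        ThermalProperties)
from .mesh import MeshControls

__all__ = ["ConfigError", "load_config", "config_from_dict", "write_timeseries",
           "read_timeseries", "write_manifest", "manifest_dict", "write_vtk"]

TIMESERIES_COLUMNS = list(TimeSeriesRecord._FIELDS)


class ConfigError(ValueError):
    pass


def _build(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"invalid value under '{path}': {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from nested plain dictionaries."""
    data = dict(data or {})
    top_known = {"probe", "domain", "mesh", "materials", "source", "run", "output"}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")

    probe = dict(data.get("probe") or {})
    concept = ProbeConcept.parse(probe.pop("concept", "single_slot"))
    dims = _build(ProbeDimensions, dict(probe.pop("dimensions", {}) or {}),
                  "probe.dimensions")
    if probe:
        raise ConfigError(f"unknown key(s) {sorted(probe)} under 'probe'")

    domain = _build(DomainSpec, dict(data.get("domain") or {}), "domain")
    mesh = _build(MeshControls, dict(data.get("mesh") or {}), "mesh")

    mat = dict(data.get("materials") or {})
    kwargs = {}
    if "sigmoid" in mat:
        kwargs["sigmoid"] = _build(SigmoidCoefficients, dict(mat.pop("sigmoid")),
                                   "materials.sigmoid")
    if "thermal" in mat:
        kwargs["thermal"] = _build(ThermalProperties, dict(mat.pop("thermal")),
                                   "materials.thermal")
    if "regions" in mat:
        kwargs["static"] = {name: _build(StaticMaterial, dict(props),
                                         f"materials.regions.{name}")
                            for name, props in dict(mat.pop("regions")).items()}
    if "property_mode" in mat:
        kwargs["property_mode"] = mat.pop("property_mode")
    if mat:
        raise ConfigError(f"unknown key(s) {sorted(mat)} under 'materials'")
    try:
        materials = MaterialAssignment(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    source = dict(data.get("source") or {})
    run = dict(data.get("run") or {})
    output = dict(data.get("output") or {})
    for sect, payload, allowed in (
            ("source", source, {"frequency", "power"}),
            ("run", run, {"duration", "dt", "sar_threshold", "temp_threshold",
                          "initial_temperature", "raster"}),
            ("output", output, {"snapshots"})):
        bad = set(payload) - allowed
        if bad:
            raise ConfigError(f"unknown key(s) {sorted(bad)} under '{sect}'")

    cfg = SimulationConfig(
        concept=concept, dims=dims, domain=domain, mesh=mesh,
        materials=materials,
        frequency=float(source.get("frequency", 2.45e9)),
        power=float(source.get("power", 30.0)),
        duration=float(run.get("duration", 300.0)),
        dt=float(run.get("dt", 5.0)),
        sar_threshold=float(run.get("sar_threshold", 1000.0)),
        temp_threshold=float(run.get("temp_threshold", 50.0)),
        initial_temperature=float(run.get("initial_temperature", 37.0)),
        raster=float(run.get("raster", 2.0e-4)),
        store_snapshots=bool(output.get("snapshots", False)),
    )
    try:
        cfg.validate()
        dims.validate(concept)
        domain.validate(dims)
        mesh.validate()
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def load_config(path) -> SimulationConfig:
    """Load a YAML run configuration; an empty file yields the full defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(data)


def write_timeseries(records, path) -> None:
    """Write per-step observables as CSV with a fixed column order."""
    if not records:
        raise ValueError("no records to write")
    df = pd.DataFrame([{k: getattr(r, k) for k in TIMESERIES_COLUMNS}
                       for r in records])
    df.to_csv(path, index=False, float_format="%.17g")


def read_timeseries(path) -> list:
    df = pd.read_csv(path)
    if list(df.columns) != TIMESERIES_COLUMNS:
        raise ValueError(f"unexpected columns {list(df.columns)}")
    return [TimeSeriesRecord(**row) for row in df.to_dict("records")]


def manifest_dict(config: SimulationConfig, mesh=None, seed=None) -> dict:
    """Fully resolved parameter record sufficient to reproduce a run."""
    from . import __version__

    def as_dict(obj):
        return dataclasses.asdict(obj) if obj is not None else None

    man = {
        "software": {"name": "mwablate", "version": __version__},
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "probe": {"concept": ProbeConcept.parse(config.concept).value,
                  "dimensions": as_dict(config.dims or ProbeDimensions())},
        "domain": as_dict(config.domain),
        "mesh_controls": as_dict(config.mesh),
        "materials": {
            "property_mode": config.materials.property_mode,
            "sigmoid": as_dict(config.materials.sigmoid),
            "thermal": as_dict(config.materials.thermal),
            "regions": {k: as_dict(v) for k, v in config.materials.static.items()},
            "reference_temperature": config.materials.reference_temperature,
        },
        "source": {"frequency": config.frequency, "power": config.power},
        "run": {"duration": config.duration, "dt": config.dt,
                "sar_threshold": config.sar_threshold,
                "temp_threshold": config.temp_threshold,
                "initial_temperature": config.initial_temperature,
                "raster": config.raster},
    }
    if seed is not None:
        man["seed"] = int(seed)
    if mesh is not None:
        man["mesh"] = {"n_vertices": int(mesh.n_vertices),
                       "n_triangles": int(mesh.n_triangles),
                       "regions": list(mesh.region_names)}
    return man


def write_manifest(config: SimulationConfig, path, mesh=None, seed=None) -> None:
    with open(path, "w") as fh:
        json.dump(manifest_dict(config, mesh=mesh, seed=seed), fh, indent=2)
        fh.write("\n")


def write_vtk(mesh, path, point_data=None, cell_data=None) -> None:
    """Write the mesh and named fields as legacy ASCII VTK (triangles).

    ``point_data`` arrays are per-vertex (P2 edge dofs are dropped);
    ``cell_data`` arrays are per-triangle.
    """
    point_data = point_data or {}
    cell_data = cell_data or {}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmwablate fields\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for r, z in mesh.vertices:
            fh.write(f"{r:.10g} {z:.10g} 0\n")
        m = mesh.n_triangles
        fh.write(f"CELLS {m} {4 * m}\n")
        for a, b, c in mesh.triangles:
            fh.write(f"3 {a} {b} {c}\n")
        fh.write(f"CELL_TYPES {m}\n")
        fh.write("\n".join(["5"] * m) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr, float)[:mesh.n_vertices]
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.10g}" for v in arr) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr, float)
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.10g}" for v in arr) + "\n")
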