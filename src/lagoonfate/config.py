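"""YAML run configuration: geometry, process constants, forcing, run control.

Every key is optional; omitted sections fall back to the packaged Thau
defaults.  Example::

    run:
      days: 365
      dt: 600
      seed: 1
    forcing:
      synthetic: true
      annual_rain_mm: 102
    geometry:
      boxes:
        - {id: west, volume: 8.12e7, area: 2.0e7, sediment_area: 2.0e7, depth: 4.06}
      connections: [[west, centre, 50.0]]
      sea_links: [[west, 10.0]]
      river_links: [[west, riv_west]]
    params:
      w_s: 1.157e-5
    ecology:
      mu_max: [2.0, 1.5]
"""

from __future__ import annotations

import dataclasses

import yaml

from . import ecology, forcing as forcing_mod, transport
from .congeners import CongenerTable
from .errors import ConfigError


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _dataclass_from(cls, mapping, label):
    mapping = mapping or {}
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"{label}: unknown keys {sorted(unknown)}")
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in mapping.items()}
    return cls(**coerced)


def geometry_from_config(cfg: dict | None) -> transport.LagoonGeometry:
    if not cfg:
        return transport.default_thau_geometry()
    boxes = [transport.Box(**b) for b in cfg.get("boxes", [])]
    if not boxes:
        raise ConfigError("geometry: at least one box required")
    return transport.LagoonGeometry(
        boxes=boxes,
        connections=[tuple(c) for c in cfg.get("connections", [])],
        sea_links=[tuple(s) for s in cfg.get("sea_links", [])],
        river_links=[tuple(r) for r in cfg.get("river_links", [])],
    )


def build_simulation(cfg: dict) -> transport.Simulation:
    """Assemble a ready-to-run Simulation from a config mapping."""
    run = cfg.get("run", {}) or {}
    days = int(run.get("days", 365))
    dt = float(run.get("dt", 600.0))
    seed = int(run.get("seed", 1))

    fcfg = cfg.get("forcing", {}) or {}
    boundary = None
    if fcfg.get("boundary_table"):
        boundary = forcing_mod.read_boundary_concentrations(fcfg["boundary_table"])
    geometry = geometry_from_config(cfg.get("geometry"))
    river_ids = tuple(sid for _, sid in geometry.river_links) or ("riv_west",)
    if fcfg.get("file"):
        frc = forcing_mod.read_forcing(fcfg["file"], step=dt, boundary=boundary)
    else:
        frc = forcing_mod.generate_synthetic_forcing(
            seed=seed, days=days, step=float(fcfg.get("step", dt)),
            annual_rain_mm=float(fcfg.get("annual_rain_mm", 102.0)),
            river_ids=river_ids, boundary=boundary)

    congeners = CongenerTable.from_tsv(cfg["congener_table"]) \
        if cfg.get("congener_table") else None
    params = _dataclass_from(transport.ProcessParams, cfg.get("params"), "params")
    eco_params = _dataclass_from(ecology.EcologyParams, cfg.get("ecology"), "ecology")
    return transport.Simulation(
        geometry=geometry, forcing=frc, congeners=congeners, params=params,
        ecology_params=eco_params, dt=dt,
        record_bin=float(run.get("record_bin", 86400.0)),
        ecology_on=bool(run.get("ecology", True)),
        sediment_dynamic=bool(run.get("sediment_dynamic", True)))
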