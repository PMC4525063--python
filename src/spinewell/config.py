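"""Run configuration, defaults provenance, and result serialization.

Configuration files are YAML with a flat, schema-checked structure; every
numeric default in the shipped material and segment tables is traceable to
its literature source through :data:`PROVENANCE`.  Unit convention for all
files: N - mm - MPa - s (segment-table inertias are kg*cm^2 and converted at
the boundary).
"""

from __future__ import annotations

import dataclasses
import datetime
import os
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import pandas as pd
import yaml

from .anatomy import GeometryConfig
from .errors import ConfigError
from .loads import DEFAULT_BODY_MASS_KG, STANDARD_GRAVITY, load_segment_table
from .muscle import DEFAULT_MATERIALS, MUSCLE_GROUPS, OPTIMAL_SARCOMERE_LENGTH_UM
from .disk import DEFAULT_DISK_MATERIALS
from .simulator import LevelSprings, ScenarioResult, build_model, summarize

__all__ = ["RunConfig", "load_config", "write_results", "model_from_config",
           "PROVENANCE"]

#: conversion used when Table-style kg*cm^2 inertias meet the N-mm-MPa-s world
KG_CM2_TO_N_MM_S2 = 100.0  # 1 kg*cm^2 = 100 N*mm*s^2 / 1000 ... documented at use


def _provenance() -> dict:
    prov = {
        "body_mass": "normal-subject body mass, 70.8 kg (anthropometric reference subject)",
        "gravity.g": "standard gravity 9.81 m/s^2",
        "muscle.A": "quadratic passive fiber constant, frog-muscle fit (Chen & Zeltzer 1992)",
        "muscle.sigma0": "maximum tetanic stress, mean of the 0.16-1 MPa skeletal-muscle range (Zajac 1989)",
        "muscle.G": "muscle matrix shear modulus (Martins et al. 1998)",
        "muscle.K": "nearly incompressible matrix, K = 1000 G (Weiss & Gardiner 2001)",
        "muscle.optimal_sarcomere_length": "optimal sarcomere length 2.8 um (Walker & Schrodt 1974; Lieber et al. 1994)",
        "disk.delta_pi": "NP-to-boundary osmotic pressure gradient 0.15 MPa (Johannessen & Elliott 2005)",
    }
    for g in MUSCLE_GROUPS:
        prov[f"muscle.C_CE1.{g}"] = (
            "concentric active parameter, strain-threshold parametric study "
            "rescaling of the sarcomere-derived value")
        prov[f"muscle.C_CE2.{g}"] = (
            "eccentric active parameter, same parametric rescaling")
        prov[f"muscle.C_CE_literature.{g}"] = (
            "sarcomere length / 2.8 um (sarcomere data reviewed by Christophy "
            "et al. 2012; Delp et al. 2001; Ward et al.)")
    for t in ("AF", "NP", "CEP"):
        for p in ("G", "K", "e0", "k0", "M"):
            prov[f"disk.{t}.{p}"] = (
                "poroelastic disk characterization (Malandrino et al.); "
                "permeability law after Argoubi & Shirazi-Adl 1996")
    for row in load_segment_table():
        src = ("head/cervical inertial data (Ivancic et al.)"
               if row.label in ("HD", "C1", "C2", "C3", "C4", "C5", "C6", "C7")
               else "thoracolumbar mass/inertia data (Pearsall et al. 1996)")
        prov[f"segments.{row.label}.bm_percent"] = src
        if row.iz is not None:
            prov[f"segments.{row.label}.iz"] = src
        if row.iz_L3 is not None:
            prov[f"segments.{row.label}.iz_L3"] = (
                "parallel-axis transfer of the Pearsall inertia to the L3/L4 axis")
        if row.r is not None:
            prov[f"segments.{row.label}.r"] = (
                "calibrated anterior-eccentricity profile (see CSV header); "
                "L4/L5 local values 11 mm / 4 mm")
    return prov


#: source of every shipped numeric default, keyed hierarchically
PROVENANCE: dict = _provenance()

_GEOMETRY_FIELDS = {f.name for f in dc_fields(GeometryConfig)}
_SPRING_FIELDS = {f.name for f in dc_fields(LevelSprings)}
_MATERIAL_OVERRIDE_KEYS = {"sigma0", "A", "G", "K"}
_SCENARIOS = {"standing", "night_rest", "swell"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with paper-table defaults filled in."""

    body_mass: float = DEFAULT_BODY_MASS_KG
    g: float = STANDARD_GRAVITY
    scenario: str = "standing"
    hours: float = 8.0
    ramp_seconds: float = 60.0
    rest_first: bool = False
    include_muscles: bool = True
    delta_pi: float = 0.15
    n_nodes: int = 9
    seed: int = 0
    output_dir: str = "results"
    newton_tol: float = 1e-8
    material_overrides: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)
    springs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.body_mass <= 0:
            raise ConfigError("body_mass must be positive")
        if self.scenario not in _SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; "
                              f"expected one of {sorted(_SCENARIOS)}")
        bad = set(self.material_overrides) - _MATERIAL_OVERRIDE_KEYS
        if bad:
            raise ConfigError(f"unknown material override keys: {sorted(bad)}")
        bad = set(self.geometry) - _GEOMETRY_FIELDS
        if bad:
            raise ConfigError(f"unknown geometry keys: {sorted(bad)}")
        bad = set(self.springs) - _SPRING_FIELDS
        if bad:
            raise ConfigError(f"unknown spring keys: {sorted(bad)}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    An empty (or absent) file yields the all-defaults configuration: 70.8 kg
    subject, shipped material tables, standing scenario.  Unknown keys are
    rejected with field-level messages.
    """
    raw = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
    allowed = {f.name for f in dc_fields(RunConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def model_from_config(config: RunConfig):
    """Build the coupled model described by a run configuration."""
    geo = GeometryConfig(**config.geometry) if config.geometry else None
    springs = LevelSprings(**config.springs) if config.springs else None
    materials = None
    if config.material_overrides:
        materials = {g: dataclasses.replace(m, **config.material_overrides)
                     for g, m in DEFAULT_MATERIALS.items()}
    return build_model(body_mass=config.body_mass,
                       include_muscles=config.include_muscles,
                       geometry_config=geo, muscle_materials=materials,
                       springs=springs, delta_pi=config.delta_pi,
                       n_nodes=config.n_nodes, g=config.g)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def write_results(result: ScenarioResult, out_dir: str | Path,
                  config: RunConfig | None = None) -> dict:
    """Serialize a scenario result to CSV tables plus a config snapshot and a
    run log.  Re-running over the same directory overwrites atomically.

    Returns the mapping of logical table name to written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = summarize(result)
    written = {}
    for name, df in tables.items():
        path = out / f"{name}.csv"
        _atomic_write(path, df.to_csv(index=False))
        written[name] = path
    if config is not None:
        snap = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
        _atomic_write(out / "config_snapshot.yaml", snap)
        written["config_snapshot"] = out / "config_snapshot.yaml"
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    n = len(result.records)
    final_t = result.records[-1]["time"] if result.records else 0.0
    log = (f"{stamp} scenario={result.scenario} steps={n} "
           f"final_time_s={final_t:.1f}\n")
    if result.records:
        for level, v in result.final()["idp"].items():
            log += f"{stamp} idp[{level}] = {v:.6f} MPa\n"
    _atomic_write(out / "run.log", log)
    written["run_log"] = out / "run.log"
    return written
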