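"""Run configuration loading and result serialisation.

A run is configured by a YAML (or JSON) file with exactly one parameter
source plus optional geometry/solver/output blocks::

    preset: fig3              # OR a physical: / dimensionless: block
    geometry: 1               # 0 slab, 1 cylinder, 2 sphere
    initial_size: 1.0
    case: 2                   # optional; validated against kappa
    solver:
      n1: 100
      n2: 100
      rtol: 1.0e-7
    outputs:
      directory: results
      snapshot_times: [1.0, 10.0]

Outputs are plain CSV/JSON (small 1D trajectories; diffable in tests), with
12 significant digits.  Dimensionless quantities are primary; when physical
parameters are supplied the times JSON additionally carries the hours per
dimensionless time unit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .parameters import (DimensionlessParameters, PhysicalParameters,
                         nondimensionalize, preset, time_unit_hours)
from .simulator import SimulationResult, SolverConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "write_result"]

_FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    """Invalid run configuration, with a field-level message."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    params: DimensionlessParameters
    solver: SolverConfig
    case: int
    outdir: Path
    physical: Optional[PhysicalParameters] = None
    preset_name: Optional[str] = None


def _parse_special_floats(block: dict) -> dict:
    out = {}
    for key, value in block.items():
        if isinstance(value, str) and value.strip().lower() in ("inf", "infinity"):
            value = math.inf
        out[key] = value
    return out


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {where}; "
            f"allowed: {sorted(allowed)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    top_allowed = {"preset", "physical", "dimensionless", "geometry",
                   "initial_size", "case", "solver", "outputs"}
    _check_keys(raw, top_allowed, "config")

    sources = [key for key in ("preset", "physical", "dimensionless") if key in raw]
    if len(sources) != 1:
        raise ConfigError(
            "exactly one of 'preset', 'physical' or 'dimensionless' must be "
            f"given; found {sources or 'none'}")

    geometry = raw.get("geometry")
    if geometry is not None and geometry not in (0, 1, 2):
        raise ConfigError(f"geometry must be 0, 1 or 2, got {geometry!r}")
    initial_size = raw.get("initial_size")

    solver_block = raw.get("solver", {}) or {}
    solver_fields = {f.name for f in dc_fields(SolverConfig)}
    _check_keys(solver_block, solver_fields, "'solver' block")
    outputs = raw.get("outputs", {}) or {}
    _check_keys(outputs, {"directory", "snapshot_times"}, "'outputs' block")
    if "snapshot_times" in outputs:
        solver_block.setdefault("snapshot_times",
                                tuple(float(t) for t in outputs["snapshot_times"]))
    try:
        solver = SolverConfig(**solver_block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid solver block: {exc}") from exc

    physical = None
    preset_name = None
    source = sources[0]
    try:
        if source == "preset":
            preset_name = raw["preset"]
            overrides = {}
            if geometry is not None:
                overrides["d"] = geometry
            if initial_size is not None:
                overrides["S0"] = float(initial_size)
            params, preset_solver = preset(preset_name, **overrides)
            for key, value in preset_solver.items():
                if key not in solver_block:
                    solver = SolverConfig(**{**solver_block, key: value})
        elif source == "physical":
            block = _parse_special_floats(raw["physical"])
            phys_fields = {f.name for f in dc_fields(PhysicalParameters)}
            _check_keys(block, phys_fields, "'physical' block")
            if initial_size is not None:
                block["S0_dim"] = float(initial_size)
            physical = PhysicalParameters(**block)
            params = nondimensionalize(physical,
                                       d=1 if geometry is None else geometry)
        else:
            block = _parse_special_floats(raw["dimensionless"])
            dim_fields = {f.name for f in dc_fields(DimensionlessParameters)}
            _check_keys(block, dim_fields - {"d"}, "'dimensionless' block")
            if geometry is not None:
                block["d"] = geometry
            if initial_size is not None:
                block["S0"] = float(initial_size)
            params = DimensionlessParameters(**block)
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc

    case = raw.get("case")
    if case is not None:
        if case not in (1, 2):
            raise ConfigError(f"case must be 1 or 2, got {case!r}")
        if case != params.case:
            raise ConfigError(
                f"case {case} inconsistent with kappa="
                f"{'inf' if params.instantaneous else params.kappa} "
                f"(which implies Case {params.case})")

    return RunConfig(
        params=params, solver=solver, case=params.case,
        outdir=Path(outputs.get("directory", "results")),
        physical=physical, preset_name=preset_name)


def write_result(result: SimulationResult, cfg: RunConfig) -> dict:
    """Write trajectory CSV, times JSON and snapshot CSVs; return the paths."""
    import pandas as pd

    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    traj = outdir / "trajectory.csv"
    result.to_frame().to_csv(traj, index=False, float_format=_FLOAT_FMT)
    paths["trajectory"] = traj

    times = dict(result.times())
    if cfg.physical is not None:
        times["time_unit_hours"] = time_unit_hours(cfg.physical)
    times_path = outdir / "times.json"
    times_path.write_text(json.dumps(times, indent=2, sort_keys=False) + "\n")
    paths["times"] = times_path

    for i, snap in enumerate(result.snapshots):
        rows = []
        if snap.r1 is not None:
            rows.append(pd.DataFrame({"zone": 1, "r": snap.r1, "W": snap.W1,
                                      "C": np.nan}))
        rows.append(pd.DataFrame({"zone": 2, "r": snap.r2, "W": snap.W2,
                                  "C": snap.C2}))
        snap_path = outdir / f"snapshot_{i:02d}_t{snap.t:.6g}.csv"
        pd.concat(rows, ignore_index=True).to_csv(
            snap_path, index=False, float_format=_FLOAT_FMT)
        paths[f"snapshot_{i}"] = snap_path
    return paths
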