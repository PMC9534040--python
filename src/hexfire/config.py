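"""Run configuration files: one YAML document describing a full simulation.

A config holds the simulator parameters, the run duration and seed, and the
paths to the input maps and schedules.  Relative paths are resolved against
the config file's own directory.  Example::

    duration: 24
    seed: 1
    params:
      burn_iterations_per_time_step: 2
      iterates_to_burn_completely: 3
      flammability_exponent: 2.0
      proximity_exponent: 0.5
      ember_creation_rate: 5
      ember_max_distance: 10
      ember_step_length_wind: 1
      ember_step_length_random: 1
    maps:
      flammability: flammability.asc
      wind_speed: wind_speed.asc
      wind_gradient: gradient.asc     # or wind_direction: dirs.asc
      barrier: barrier.asc            # optional 0/1 mask
    schedules:
      ignitions: ignitions.csv        # optional, time_step,row,col
      fuel_breaks: breaks.csv         # optional
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .fire_engine import SimParams
from .hexgrid import read_ascii_grid
from .landscape import (
    FuelBreakSchedule,
    IgnitionSchedule,
    LandscapeMaps,
    Schedules,
    load_schedule_csv,
    validate,
)
from .windfield import build_gradient

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    maps: LandscapeMaps
    schedules: Schedules
    params: SimParams
    duration: int
    seed: int | None


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, reading every referenced file."""
    path = Path(path)
    base = path.parent
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")

    params = SimParams.from_dict(doc.get("params", {}))
    duration = int(doc.get("duration", 1))
    seed = doc.get("seed")
    seed = None if seed is None else int(seed)

    map_paths = doc.get("maps", {})
    if "flammability" not in map_paths:
        raise ValueError(f"{path}: maps.flammability is required")
    flam = read_ascii_grid(base / map_paths["flammability"])
    if "wind_speed" in map_paths:
        speed = read_ascii_grid(base / map_paths["wind_speed"])
    else:
        speed = flam.copy()
        speed.values[:] = 0.0  # windless by default: purely contagious spread
    if "wind_gradient" in map_paths:
        grad = read_ascii_grid(base / map_paths["wind_gradient"])
    elif "wind_direction" in map_paths:
        dirs = read_ascii_grid(base / map_paths["wind_direction"])
        grad = build_gradient(dirs, smooth_iters=int(doc.get("gradient_smooth", 0)))
    else:
        grad = flam.copy()
        grad.values[:] = 0.0
    barrier = (
        read_ascii_grid(base / map_paths["barrier"])
        if "barrier" in map_paths
        else None
    )
    maps = LandscapeMaps.from_maps(flam, speed, grad, barrier)
    diags = validate(maps)
    if diags:
        raise ValueError(f"{path}: invalid input maps: " + "; ".join(diags))

    sched_paths = doc.get("schedules", {})
    ign = IgnitionSchedule()
    brk = FuelBreakSchedule()
    if "ignitions" in sched_paths:
        ign = load_schedule_csv(base / sched_paths["ignitions"], maps.grid, "ignition")
    if "fuel_breaks" in sched_paths:
        brk = load_schedule_csv(
            base / sched_paths["fuel_breaks"], maps.grid, "fuel_break"
        )
    return RunConfig(maps, Schedules(ign, brk), params, duration, seed)
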