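"""Input layers for the fire simulator: flammability, wind, barriers, schedules.

A simulation consumes four per-cell layers sharing one grid — relative
flammability F in [0, 1] (0 = no fuel, 1 = the most flammable fuel), relative
wind speed S in [0, 1], a wind-gradient potential G (embers climb from low to
high G), and a boolean fuel-barrier mask — plus two time-indexed schedules:
ignitions (including back burns) and fuel breaks.  Fuel breaks permanently
remove fuel (F := 0) at scheduled cells and times; they stop future ignition
but do not extinguish cells already burning.

The synthetic generators fabricate the study landscapes used throughout:
a checkerboard of high/low-flammability blocks, a smoothed-random field with
an exaggerated upper tail, and uniform wind fields.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hexgrid import CellIndex, CellMap, GridSpec, neighbor_table

__all__ = [
    "LandscapeMaps",
    "IgnitionSchedule",
    "FuelBreakSchedule",
    "Schedules",
    "validate",
    "gen_checkerboard",
    "gen_smoothed_random",
    "gen_uniform_wind",
    "apply_fuel_breaks",
    "load_schedule_csv",
    "save_schedule_csv",
    "hex_smooth",
]


@dataclass
class LandscapeMaps:
    """All per-cell input layers, sharing one :class:`GridSpec`."""

    grid: GridSpec
    flammability: np.ndarray
    wind_speed: np.ndarray
    wind_gradient: np.ndarray
    barrier: np.ndarray

    def __post_init__(self) -> None:
        self.flammability = np.asarray(self.flammability, dtype=float)
        self.wind_speed = np.asarray(self.wind_speed, dtype=float)
        self.wind_gradient = np.asarray(self.wind_gradient, dtype=float)
        self.barrier = np.asarray(self.barrier, dtype=bool)

    @classmethod
    def from_maps(
        cls,
        flammability: CellMap,
        wind_speed: CellMap,
        wind_gradient: CellMap,
        barrier: CellMap | None = None,
    ) -> "LandscapeMaps":
        grid = flammability.grid
        if barrier is None:
            bmask = np.zeros(grid.shape, dtype=bool)
        else:
            bmask = barrier.values != 0
        return cls(
            grid,
            flammability.values,
            wind_speed.values,
            wind_gradient.values,
            bmask,
        )

    def copy(self) -> "LandscapeMaps":
        return LandscapeMaps(
            self.grid,
            self.flammability.copy(),
            self.wind_speed.copy(),
            self.wind_gradient.copy(),
            self.barrier.copy(),
        )


@dataclass
class _Schedule:
    """Time-indexed list of (time_step, cell) events."""

    entries: list[tuple[int, CellIndex]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = [
            (int(t), CellIndex(int(c[0]), int(c[1]))) for t, c in self.entries
        ]
        for t, cell in self.entries:
            if t < 0:
                raise ValueError(f"negative time step {t} in schedule")

    def cells_at(self, t: int) -> list[CellIndex]:
        return [cell for ts, cell in self.entries if ts == t]

    def check_bounds(self, grid: GridSpec) -> None:
        for t, cell in self.entries:
            if not grid.contains(cell):
                raise ValueError(
                    f"scheduled cell {tuple(cell)} outside {grid.rows}x{grid.cols} grid"
                )

    def __len__(self) -> int:
        return len(self.entries)


class IgnitionSchedule(_Schedule):
    """When and where fires (including back burns) are set."""


class FuelBreakSchedule(_Schedule):
    """When and where fuel is removed from the landscape (F set to 0)."""


@dataclass
class Schedules:
    ignitions: IgnitionSchedule = field(default_factory=IgnitionSchedule)
    fuel_breaks: FuelBreakSchedule = field(default_factory=FuelBreakSchedule)


def validate(maps: LandscapeMaps) -> list[str]:
    """Check all layers for range and shape problems.

    Returns a list of human-readable diagnostics (empty when all is well).
    Shape mismatches between layers are fatal and raise immediately; range
    violations and NaNs are reported but left to the caller.
    """
    shape = maps.grid.shape
    for name in ("flammability", "wind_speed", "wind_gradient", "barrier"):
        layer = getattr(maps, name)
        if layer.shape != shape:
            raise ValueError(
                f"{name} shape {layer.shape} does not match grid {shape}"
            )
    diags: list[str] = []
    for name, lo, hi in (("flammability", 0.0, 1.0), ("wind_speed", 0.0, 1.0)):
        layer = getattr(maps, name)
        bad = (layer < lo) | (layer > hi)
        if bad.any():
            n = int(bad.sum())
            r, c = np.argwhere(bad)[0]
            diags.append(
                f"{name}: {n} cells outside [{lo}, {hi}] "
                f"(first at ({r}, {c}) = {layer[r, c]})"
            )
    for name in ("flammability", "wind_speed", "wind_gradient"):
        layer = getattr(maps, name)
        if np.isnan(layer).any():
            diags.append(f"{name}: {int(np.isnan(layer).sum())} NaN cells")
    return diags


def gen_checkerboard(
    rows: int, cols: int, block: int, hi: float = 1.0, lo: float = 0.25
) -> CellMap:
    """Checkerboard flammability map of ``block``-sided square blocks.

    Cell (r, c) gets ``hi`` when floor(r/block) + floor(c/block) is even,
    ``lo`` otherwise.  The default 1.00/0.25 alternation juxtaposes the most
    flammable fuel with a low-flammability matrix.  ``rows`` and ``cols``
    must be divisible by ``block``.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    if rows % block or cols % block:
        raise ValueError(
            f"grid {rows}x{cols} not divisible into {block}x{block} blocks"
        )
    r_idx = np.arange(rows)[:, None] // block
    c_idx = np.arange(cols)[None, :] // block
    values = np.where((r_idx + c_idx) % 2 == 0, float(hi), float(lo))
    return CellMap(GridSpec(rows, cols), values)


def hex_smooth(values: np.ndarray, grid: GridSpec, iters: int) -> np.ndarray:
    """``iters`` passes of mean smoothing over each cell and its <=6 neighbors."""
    if iters < 0:
        raise ValueError("iters must be >= 0")
    nr, nc, valid = neighbor_table(grid)
    out = np.asarray(values, dtype=float).copy()
    denom = valid.sum(axis=2) + 1.0
    for _ in range(iters):
        acc = out.copy()
        gathered = out[nr, nc]
        gathered[~valid] = 0.0
        acc += gathered.sum(axis=2)
        out = acc / denom
    return out


def gen_smoothed_random(
    rows: int,
    cols: int,
    n_points: int,
    smooth_iters: int,
    exaggeration: float,
    seed: int,
) -> CellMap:
    """Smoothed-random flammability field with an inflated upper tail.

    ``n_points`` cells are seeded at 1.0 on a zero field, smoothed by
    ``smooth_iters`` passes of hex-neighborhood mean smoothing, rescaled to
    [0, 1], then transformed by v -> v**(1/exaggeration).  With
    exaggeration > 1 this concave power law exaggerates the number of large
    values, producing patchy but extensive fuels.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if smooth_iters < 0:
        raise ValueError("smooth_iters must be >= 0")
    if exaggeration < 1.0:
        raise ValueError("exaggeration must be >= 1")
    grid = GridSpec(rows, cols)
    rng = np.random.default_rng(seed)
    values = np.zeros(grid.shape)
    picks = rng.choice(rows * cols, size=min(n_points, rows * cols), replace=False)
    values.flat[picks] = 1.0
    values = hex_smooth(values, grid, smooth_iters)
    vmax = values.max()
    if vmax > 0:
        values = values / vmax
    if exaggeration != 1.0:
        values = values ** (1.0 / exaggeration)
    return CellMap(grid, values)


def gen_uniform_wind(
    rows: int, cols: int, speed: float, bearing_deg: float
) -> tuple[CellMap, CellMap]:
    """Constant wind-speed and wind-direction maps.

    ``bearing_deg`` is the direction the wind blows toward, clockwise from
    grid-north (0 = north/up, 90 = east, 180 = south/down).
    """
    if not 0.0 <= speed <= 1.0:
        raise ValueError(f"wind speed {speed} outside [0, 1]")
    grid = GridSpec(rows, cols)
    bearing = float(bearing_deg) % 360.0
    return CellMap.full(grid, speed), CellMap.full(grid, bearing)


def apply_fuel_breaks(
    maps: LandscapeMaps, schedule: FuelBreakSchedule, t: int
) -> np.ndarray:
    """Remove fuel (F := 0, in place) at cells scheduled for time step ``t``.

    Fuel removal is permanent and idempotent; cells not in the schedule are
    untouched, and already-burning cells are unaffected (removal only
    prevents future ignition).  Returns the updated flammability array.
    """
    for cell in schedule.cells_at(t):
        maps.flammability[cell.row, cell.col] = 0.0
    return maps.flammability


def load_schedule_csv(
    path: str | Path, grid: GridSpec, kind: str = "ignition"
) -> IgnitionSchedule | FuelBreakSchedule:
    """Load a ``time_step,row,col`` CSV as a bounds-checked schedule."""
    cls = {"ignition": IgnitionSchedule, "fuel_break": FuelBreakSchedule}[kind]
    entries: list[tuple[int, CellIndex]] = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"time_step", "row", "col"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected CSV header with columns {sorted(required)}"
            )
        for rec in reader:
            t = int(rec["time_step"])
            cell = CellIndex(int(rec["row"]), int(rec["col"]))
            if t < 0:
                raise ValueError(f"{path}: negative time step {t}")
            entries.append((t, cell))
    sched = cls(entries)
    sched.check_bounds(grid)
    return sched


def save_schedule_csv(schedule: _Schedule, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_step", "row", "col"])
        for t, cell in schedule.entries:
            writer.writerow([t, cell.row, cell.col])
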