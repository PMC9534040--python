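"""Replicate experiments: batch runs, burn-frequency maps, fire-size statistics.

A scenario bundles a landscape builder, schedules, parameters, and a run
duration.  Replicates are independent seeded runs (replicate r uses seed
``base_seed + r``); the per-cell burn frequency over a batch is the exact
fraction of replicates in which the cell burned (cells still burning at the
final step count as burned — end-of-run snapshots necessarily include active
fire).

The module ships the six parameter-exploration scenarios of the checkerboard
experiment (A baseline, B hotter exponents, C colder exponents, D longer
ember range, E wind-tracking embers, F wandering embers) plus their B+D+F
hybrid, and the summary statistics used to compare them: mean burned area,
downwind extent, and crosswind footprint width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats

from .fire_engine import BurnOutcome, SimParams, Simulation
from .hexgrid import CellIndex, CellMap, GridSpec
from .landscape import (
    IgnitionSchedule,
    LandscapeMaps,
    Schedules,
    gen_checkerboard,
    gen_uniform_wind,
)
from .windfield import build_gradient

__all__ = [
    "BurnFrequencyMap",
    "Scenario",
    "run_replicates",
    "burn_frequency",
    "fire_size_distribution",
    "collect_fire_sizes",
    "example1_scenarios",
    "footprint_metrics",
    "unburnt_fraction",
]


@dataclass
class BurnFrequencyMap:
    """Per-cell fraction of replicates in which the cell burned."""

    grid: GridSpec
    values: np.ndarray
    n_replicates: int

    def as_cellmap(self) -> CellMap:
        return CellMap(self.grid, self.values)


@dataclass
class Scenario:
    """A named, reproducible experimental setup.

    ``builder`` constructs the landscape and schedules fresh on demand so a
    scenario object stays cheap to create and serialize-free; parameters are
    plain :class:`SimParams` overrides on the baseline.
    """

    name: str
    params: SimParams
    builder: Callable[[], tuple[LandscapeMaps, Schedules]]
    duration: int
    n_replicates: int = 100
    _cache: tuple[LandscapeMaps, Schedules] | None = field(
        default=None, repr=False, compare=False
    )

    def build(self) -> tuple[LandscapeMaps, Schedules]:
        if self._cache is None:
            self._cache = self.builder()
        return self._cache


def run_replicates(
    scenario: Scenario, n: int, base_seed: int
) -> list[BurnOutcome]:
    """Run ``n`` independent replicates; replicate r uses seed base_seed + r."""
    if n < 1:
        raise ValueError("n must be >= 1")
    maps, schedules = scenario.build()
    sim = Simulation(maps, schedules, scenario.params)
    return [sim.run(scenario.duration, seed=base_seed + r) for r in range(n)]


def burn_frequency(outcomes: list[BurnOutcome]) -> BurnFrequencyMap:
    """Per-cell burn frequency over a batch of outcomes (exact count ratio)."""
    if not outcomes:
        raise ValueError("need at least one outcome")
    grid = outcomes[0].grid
    counts = np.zeros(grid.shape, dtype=np.int64)
    for o in outcomes:
        if o.grid != grid:
            raise ValueError("outcomes computed on different grids")
        counts += o.burned_mask
    return BurnFrequencyMap(grid, counts / len(outcomes), len(outcomes))


def fire_size_distribution(
    outcomes: list[BurnOutcome], min_size: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Burned-cell counts per outcome and a needs-replacement flag.

    Outcomes smaller than ``min_size`` hexagons are trivial fires (typically
    ignitions that failed to catch) and are flagged for replacement; use
    :func:`collect_fire_sizes` to rerun until a quota of nontrivial outcomes
    is reached.
    """
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    sizes = np.array([o.burned_cells for o in outcomes], dtype=np.int64)
    return sizes, sizes < min_size


def collect_fire_sizes(
    scenario: Scenario,
    quota: int,
    min_size: int,
    base_seed: int,
    keep_outcomes: bool = False,
    max_attempts: int | None = None,
) -> tuple[np.ndarray, list[BurnOutcome]]:
    """Run replicates until ``quota`` fires of at least ``min_size`` hexagons.

    Trivial outcomes (final burn area < min_size) are discarded and replaced
    with results from additional replicates.  Seeds advance one per attempt
    from ``base_seed`` so the collection is reproducible.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    maps, schedules = scenario.build()
    sim = Simulation(maps, schedules, scenario.params)
    if max_attempts is None:
        max_attempts = 100 * quota
    sizes: list[int] = []
    kept: list[BurnOutcome] = []
    attempt = 0
    while len(sizes) < quota:
        if attempt >= max_attempts:
            raise RuntimeError(
                f"quota {quota} not reached after {attempt} attempts "
                f"({len(sizes)} nontrivial fires)"
            )
        outcome = sim.run(scenario.duration, seed=base_seed + attempt)
        attempt += 1
        if outcome.burned_cells >= min_size:
            sizes.append(outcome.burned_cells)
            if keep_outcomes:
                kept.append(outcome)
    return np.array(sizes, dtype=np.int64), kept


# ---------------------------------------------------------------------------
# checkerboard parameter-exploration scenarios

BASELINE = SimParams()  # see SimParams docstring for the baseline values

_VARIANT_OVERRIDES: dict[str, dict] = {
    "A": {},
    "B": {"flammability_exponent": 5.0, "proximity_exponent": 0.2},
    "C": {"flammability_exponent": 0.2, "proximity_exponent": 5.0},
    "D": {"ember_max_distance": 50},
    "E": {"ember_step_length_wind": 10},
    "F": {"ember_step_length_random": 10},
    # hybrid: B's exponents + D's ember range + F's step lengths
    "hybrid": {
        "flammability_exponent": 5.0,
        "proximity_exponent": 0.2,
        "ember_max_distance": 50,
        "ember_step_length_random": 10,
    },
}


def _checkerboard_builder(
    rows: int, cols: int, block: int
) -> Callable[[], tuple[LandscapeMaps, Schedules]]:
    def build() -> tuple[LandscapeMaps, Schedules]:
        flam = gen_checkerboard(rows, cols, block, hi=1.0, lo=0.25)
        speed, dirs = gen_uniform_wind(rows, cols, 1.0, 180.0)  # due south
        grad = build_gradient(dirs)
        maps = LandscapeMaps.from_maps(flam, speed, grad)
        # top-center ignition; with an even column count the center line falls
        # between two cells, and the tie goes to the high-flammability block
        # so the fire reliably catches under every parameter variant
        candidates = [cols // 2, max(cols // 2 - 1, 0)]
        col = max(candidates, key=lambda c: flam.values[0, c])
        ign = IgnitionSchedule([(0, CellIndex(0, col))])
        return maps, Schedules(ignitions=ign)

    return build


def example1_scenarios(
    rows: int = 500,
    cols: int = 500,
    block: int = 10,
    duration: int = 24,
    n_replicates: int = 100,
) -> dict[str, Scenario]:
    """The checkerboard parameter-study scenarios (A-F plus the hybrid).

    The landscape is a checkerboard of 10x10-hexagon blocks alternating
    between flammability 1.00 and 0.25, uniform wind speed 1 with the
    gradient directing embers due south, a single top-center ignition at
    step 0, and a one-day (24 time step) run.  Variants override the
    baseline: B/C trade the flammability and proximity exponents, D extends
    the ember range, E makes embers track the wind, F makes them wander.
    """
    builder = _checkerboard_builder(rows, cols, block)
    out = {}
    for name, overrides in _VARIANT_OVERRIDES.items():
        out[name] = Scenario(
            name=f"example1-{name}",
            params=BASELINE.replace(**overrides),
            builder=builder,
            duration=duration,
            n_replicates=n_replicates,
        )
    return out


# ---------------------------------------------------------------------------
# footprint summaries

def footprint_metrics(
    freq: BurnFrequencyMap,
    threshold: float = 0.05,
    burnable: np.ndarray | None = None,
) -> dict[str, float]:
    """Summary statistics of a burn-frequency (or single-run 0/1) map.

    * ``mean_burned_fraction`` — mean frequency over burnable cells (all
      cells if no burnable mask is given);
    * ``downwind_extent`` — number of rows from the top of the map to the
      deepest row with any cell at frequency >= threshold (wind blows
      toward increasing row index in the checkerboard setup);
    * ``crosswind_width`` — longest contiguous run of columns containing at
      least one cell at frequency >= threshold.
    """
    v = freq.values
    hit = v >= threshold
    if burnable is None:
        mean_frac = float(v.mean())
    else:
        mean_frac = float(v[burnable].mean()) if burnable.any() else 0.0
    if not hit.any():
        return {
            "mean_burned_fraction": mean_frac,
            "downwind_extent": 0.0,
            "crosswind_width": 0.0,
        }
    rows_hit = np.flatnonzero(hit.any(axis=1))
    cols_hit = hit.any(axis=0)
    # longest contiguous run of True columns
    padded = np.concatenate(([False], cols_hit, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = edges[1::2] - edges[::2]
    return {
        "mean_burned_fraction": mean_frac,
        "downwind_extent": float(rows_hit.max() + 1),
        "crosswind_width": float(runs.max()),
    }


def outcome_metrics(outcome: BurnOutcome) -> dict[str, float]:
    """Footprint metrics of a single run (its 0/1 burn indicator)."""
    ind = BurnFrequencyMap(outcome.grid, outcome.burned_mask.astype(float), 1)
    m = footprint_metrics(ind, threshold=0.5)
    m["burned_cells"] = float(outcome.burned_cells)
    return m


def unburnt_fraction(freq: BurnFrequencyMap, flammability: np.ndarray) -> float:
    """Fraction of burnable (F > 0) cells that never burned in any replicate."""
    if freq.values.shape != flammability.shape:
        raise ValueError("frequency map and flammability map shapes differ")
    burnable = flammability > 0
    n_burnable = int(burnable.sum())
    if n_burnable == 0:
        return 0.0
    never = (freq.values == 0) & burnable
    return int(never.sum()) / n_burnable


def mannwhitney_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Mann-Whitney p-value for 'x stochastically exceeds y'."""
    return float(stats.mannwhitneyu(x, y, alternative="greater").pvalue)
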