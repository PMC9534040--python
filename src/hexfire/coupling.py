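"""Coupling fire disturbance to a habitat-based population model.

The fire simulator is linked to an ecological model indirectly, through
files: many fire realizations are run to completion, their final burn maps
collected into a disturbance library, and each population replicate draws
one burn from the library, zeroes habitat quality throughout the burned
area, and removes any individuals located there (a worst-case scenario in
which animals cannot escape the fire).  Indirect coupling lets models with
different temporal increments — hourly fire steps versus yearly population
steps — be combined without code integration.

The population model here is deliberately simple: a territory-free
stochastic logistic (Ricker with demographic noise) whose carrying capacity
is proportional to summed habitat quality.  It preserves the experimental
design of the coupling — disturbance before year 1, steady-state comparison
against undisturbed runs — while making no attempt to reproduce any
particular species' demography.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .experiments import Scenario, collect_fire_sizes
from .fire_engine import BurnOutcome, UNBURNED
from .hexgrid import CellIndex, CellMap, GridSpec, read_ascii_grid, write_ascii_grid

__all__ = [
    "HabitatMap",
    "DisturbanceLibrary",
    "apply_burn",
    "remove_agents",
    "toy_population_run",
    "build_library",
    "save_library",
    "load_library",
]

HabitatMap = CellMap  # per-cell habitat quality, non-negative real


def _burn_mask(burn: BurnOutcome | CellMap | np.ndarray) -> np.ndarray:
    if isinstance(burn, BurnOutcome):
        return burn.burned_mask
    if isinstance(burn, CellMap):
        return burn.values != UNBURNED
    return np.asarray(burn) != 0


def apply_burn(habitat: HabitatMap, burn) -> HabitatMap:
    """Zero habitat quality throughout the burned area (new map returned).

    Idempotent, never increases quality, and leaves unburned cells
    untouched.
    """
    mask = _burn_mask(burn)
    if mask.shape != habitat.grid.shape:
        raise ValueError(
            f"burn shape {mask.shape} does not match habitat {habitat.grid.shape}"
        )
    values = habitat.values.copy()
    values[mask] = 0.0
    return CellMap(habitat.grid, values)


def remove_agents(
    agents: list[CellIndex], burn
) -> list[CellIndex]:
    """Drop every individual located inside the burned area."""
    mask = _burn_mask(burn)
    return [a for a in agents if not mask[a[0], a[1]]]


@dataclass
class DisturbanceLibrary:
    """A collection of final burn maps with seed/size metadata."""

    grid: GridSpec
    burns: list[np.ndarray]  # boolean burned masks
    seeds: list[int]
    sizes: list[int]  # burned hexagons per entry
    min_size: int = 0

    def __post_init__(self) -> None:
        if not (len(self.burns) == len(self.seeds) == len(self.sizes)):
            raise ValueError("burns, seeds and sizes must align")
        for s in self.sizes:
            if s < self.min_size:
                raise ValueError(
                    f"library entry of size {s} below minimum {self.min_size}"
                )

    def __len__(self) -> int:
        return len(self.burns)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.burns[int(rng.integers(len(self.burns)))]


def build_library(
    scenario: Scenario, quota: int, min_size: int, base_seed: int
) -> DisturbanceLibrary:
    """Assemble ``quota`` nontrivial burn realizations from a fire scenario.

    Fires smaller than ``min_size`` hexagons (ignitions that failed to
    catch) are replaced with additional replicates until the quota of
    nontrivial outcomes is met.
    """
    sizes, outcomes = collect_fire_sizes(
        scenario, quota, min_size, base_seed, keep_outcomes=True
    )
    maps, _ = scenario.build()
    return DisturbanceLibrary(
        grid=maps.grid,
        burns=[o.burned_mask for o in outcomes],
        seeds=[o.seed for o in outcomes],
        sizes=[int(s) for s in sizes],
        min_size=min_size,
    )


def save_library(library: DisturbanceLibrary, out_dir: str | Path) -> None:
    """Write a library as a directory of ASCII burn grids plus a CSV manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with (out / "manifest.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "seed", "size", "min_size"])
        for i, (burn, seed, size) in enumerate(
            zip(library.burns, library.seeds, library.sizes)
        ):
            name = f"burn_{i:04d}.asc"
            write_ascii_grid(
                CellMap(library.grid, burn.astype(float)), out / name
            )
            writer.writerow([name, seed, size, library.min_size])


def load_library(lib_dir: str | Path) -> DisturbanceLibrary:
    lib = Path(lib_dir)
    burns, seeds, sizes = [], [], []
    min_size = 0
    grid: GridSpec | None = None
    with (lib / "manifest.csv").open(newline="") as fh:
        for rec in csv.DictReader(fh):
            cmap = read_ascii_grid(lib / rec["file"])
            if grid is None:
                grid = cmap.grid
            burns.append(cmap.values != 0)
            seeds.append(int(rec["seed"]))
            sizes.append(int(rec["size"]))
            min_size = int(rec["min_size"])
    if grid is None:
        raise ValueError(f"empty library manifest in {lib}")
    return DisturbanceLibrary(grid, burns, seeds, sizes, min_size)


def toy_population_run(
    habitat: HabitatMap,
    disturbance=None,
    years: int = 50,
    growth_rate: float = 0.3,
    k_per_quality: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Yearly population sizes under an optional year-0 fire disturbance.

    Carrying capacity K is proportional to summed habitat quality
    (``k_per_quality`` individuals per quality unit).  The population starts
    at the undisturbed K; the disturbance (a burn map) is applied before
    year 1, zeroing quality in the burned area and removing the individuals
    that lived there (removals in proportion to the habitat lost).
    Dynamics are Ricker with demographic noise:

        N(t+1) ~ Poisson( N(t) * exp(r * (1 - N(t) / K)) ).

    Returns an array of length ``years + 1`` (year 0 = initial population).
    A population with zero habitat is extinct by year 1.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    k0 = k_per_quality * float(habitat.values.sum())
    n = np.zeros(years + 1)
    n[0] = np.floor(k0)
    if disturbance is not None:
        disturbed = apply_burn(habitat, disturbance)
        k = k_per_quality * float(disturbed.values.sum())
        # worst case: everyone inside the burn dies with their habitat
        n[0] = np.floor(n[0] * (k / k0)) if k0 > 0 else 0.0
    else:
        k = k0
    for t in range(years):
        if n[t] <= 0 or k <= 0:
            n[t + 1] = 0.0
            continue
        expected = n[t] * np.exp(growth_rate * (1.0 - n[t] / k))
        n[t + 1] = float(rng.poisson(expected))
    return n
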