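"""Core fire dynamics: contagious spread, ember spotting, burn progression.

The model is a stochastic cellular automaton on a hexagonal lattice coupled
with ember agents.  Each cell is UNBURNED, BURNING, or BURNED (absorbing).
Fire spreads by two mechanisms:

* **Contagion** — an unburned cell with N burning neighbors (0-6) ignites
  with probability

      P_contagion = P_proximity * P_flammability
      P_proximity = 1 - (1 - N/6)**alpha
      P_flammability = 1 - (1 - F)**beta

  where F is the cell's relative flammability and alpha, beta are the
  proximity and flammability exponents.  Any positive exponents yield
  nontrivial, strictly increasing probability curves.

* **Fire spotting** — every actively burning cell emits up to
  round(F * epsilon) embers per burn iteration (epsilon = ember creation
  rate); the realized count is uniform on {0, ..., max}.  Each ember is
  assigned a travel distance D = round(U(0, S * delta)) hexagons (S = local
  relative wind speed, delta = ember max distance) and flies by alternating
  wind steps (up to L_w hexagons climbing the wind gradient) with random
  steps (a straight run of up to L_r hexagons in one uniformly drawn
  direction), until it has traveled D hexagons.  Moves into fuel-barrier
  cells are refused and end the flight; moves off the grid extinguish the
  ember.  A landing ember ignites an unburned cell with probability
  P_flammability.

Several burn iterations make up one model time step (the
``burn_iterations_per_time_step`` parameter); an ignited cell stays an
active fire source for ``iterates_to_burn_completely`` iterations.  Updates
are synchronous: contagion and ember emission both read the state at
iteration entry, and new ignitions only become active the next iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Any

import numpy as np
import pandas as pd

from .hexgrid import CellIndex, GridSpec, neighbor_count
from .landscape import LandscapeMaps, Schedules, apply_fuel_breaks
from .windfield import uphill_neighbor
from . import hexgrid

__all__ = [
    "UNBURNED",
    "BURNING",
    "BURNED",
    "SimParams",
    "SimState",
    "Ember",
    "BurnOutcome",
    "p_proximity",
    "p_flammability",
    "p_contagion",
    "contagion_iteration",
    "emit_embers",
    "move_ember",
    "land_ember",
    "advance_burning",
    "time_step",
    "run_simulation",
    "Simulation",
]

UNBURNED, BURNING, BURNED = 0, 1, 2


@dataclass(frozen=True)
class SimParams:
    """The eight core simulator parameters plus optional settings.

    Defaults are the baseline parameterization used throughout the worked
    examples: 2 burn iterations per hourly time step, 3 iterates to burn
    completely, flammability exponent beta = 2, proximity exponent
    alpha = 0.5, ember creation rate epsilon = 5, ember max distance
    delta = 10 hexagons, and unit wind/random ember step lengths.
    """

    burn_iterations_per_time_step: int = 2
    iterates_to_burn_completely: int = 3
    flammability_exponent: float = 2.0  # beta
    proximity_exponent: float = 0.5  # alpha
    ember_creation_rate: float = 5.0  # epsilon
    ember_max_distance: int = 10  # delta, hexagons
    ember_step_length_wind: int = 1
    ember_step_length_random: int = 1
    random_fires_min: int = 0
    random_fires_max: int = 0
    early_termination: bool = False
    output_mode: str = "final"  # "final" | "per_step"

    def __post_init__(self) -> None:
        if self.burn_iterations_per_time_step < 1:
            raise ValueError("burn_iterations_per_time_step must be >= 1")
        if self.iterates_to_burn_completely < 1:
            raise ValueError("iterates_to_burn_completely must be >= 1")
        if self.flammability_exponent <= 0 or self.proximity_exponent <= 0:
            raise ValueError("flammability and proximity exponents must be > 0")
        if self.ember_creation_rate < 0:
            raise ValueError("ember_creation_rate must be >= 0")
        for name in (
            "ember_max_distance",
            "ember_step_length_wind",
            "ember_step_length_random",
            "random_fires_min",
            "random_fires_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.random_fires_min > self.random_fires_max:
            raise ValueError("random_fires_min must be <= random_fires_max")
        if self.output_mode not in ("final", "per_step"):
            raise ValueError("output_mode must be 'final' or 'per_step'")

    def replace(self, **overrides: Any) -> "SimParams":
        return _dc_replace(self, **overrides)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimParams":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Ember:
    """A wind-lofted firebrand with an assigned travel distance in hexagons."""

    position: CellIndex
    assigned_distance: int
    traveled: int = 0


@dataclass
class SimState:
    """Per-cell combustion state plus the simulation clock."""

    grid: GridSpec
    state: np.ndarray  # uint8: UNBURNED/BURNING/BURNED
    remaining: np.ndarray  # burn iterates left; meaningful only while BURNING
    clock: tuple[int, int] = (0, 0)  # (time_step, iteration within step)

    @classmethod
    def initial(cls, grid: GridSpec) -> "SimState":
        return cls(
            grid,
            np.full(grid.shape, UNBURNED, dtype=np.uint8),
            np.zeros(grid.shape, dtype=np.int32),
        )

    def ignite(self, cell: CellIndex, params: SimParams) -> None:
        """Force-ignite an unburned cell (scheduled ignitions, back burns)."""
        r, c = cell
        if self.state[r, c] == UNBURNED:
            self.state[r, c] = BURNING
            self.remaining[r, c] = params.iterates_to_burn_completely

    @property
    def burning(self) -> np.ndarray:
        return self.state == BURNING

    @property
    def burned_or_burning(self) -> np.ndarray:
        return self.state != UNBURNED

    def copy(self) -> "SimState":
        return SimState(self.grid, self.state.copy(), self.remaining.copy(), self.clock)


# ---------------------------------------------------------------------------
# spread probabilities

def p_proximity(n, alpha: float):
    """P = 1 - (1 - N/6)**alpha for N burning neighbors out of 6."""
    n_arr = np.asarray(n, dtype=float)
    if np.any((n_arr < 0) | (n_arr > 6)):
        raise ValueError("burning-neighbor count N must be in [0, 6]")
    if alpha <= 0:
        raise ValueError("proximity exponent must be > 0")
    out = 1.0 - (1.0 - n_arr / 6.0) ** alpha
    return float(out) if np.isscalar(n) else out


def p_flammability(f, beta: float):
    """P = 1 - (1 - F)**beta for relative flammability F in [0, 1]."""
    f_arr = np.asarray(f, dtype=float)
    if np.any((f_arr < 0) | (f_arr > 1)):
        raise ValueError("relative flammability F must be in [0, 1]")
    if beta <= 0:
        raise ValueError("flammability exponent must be > 0")
    out = 1.0 - (1.0 - f_arr) ** beta
    return float(out) if np.isscalar(f) else out


def p_contagion(n, f, alpha: float, beta: float):
    """Probability that an unburned cell ignites this iteration by contagion."""
    return p_proximity(n, alpha) * p_flammability(f, beta)


def _round(x):
    # round-half-to-even; the model only specifies "rounded to an integer"
    return np.rint(x).astype(np.int64)


# ---------------------------------------------------------------------------
# single-iteration operations (spec surface; the Simulation class below uses
# vectorized equivalents drawing from the same per-replicate generator)

def contagion_iteration(
    state: SimState,
    maps: LandscapeMaps,
    params: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One synchronous contagion pass; returns uncommitted ignitions.

    N is counted against the cell states at iteration entry; every unburned
    cell with N >= 1 ignites independently with probability P_contagion.
    Uniform draws are made for candidate cells in row-major order.  The
    returned boolean mask is NOT committed to ``state`` — newly ignited
    cells must not spread or emit until the next iteration.
    """
    n = neighbor_count(state.burning)
    cand = (state.state == UNBURNED) & (n > 0)
    ignitions = np.zeros(state.grid.shape, dtype=bool)
    idx = np.flatnonzero(cand.ravel())
    if len(idx) == 0:
        return ignitions
    p = p_contagion(
        n.ravel()[idx],
        maps.flammability.ravel()[idx],
        params.proximity_exponent,
        params.flammability_exponent,
    )
    draws = rng.random(len(idx))
    ignitions.ravel()[idx[draws < p]] = True
    return ignitions


def emit_embers(
    cell: CellIndex,
    f: float,
    s: float,
    params: SimParams,
    rng: np.random.Generator,
) -> list[Ember]:
    """Embers emitted by one burning cell in one iteration.

    The cell creates between zero and round(F * epsilon) embers (uniform on
    that range); each receives a travel distance D = round(U(0, S * delta))
    hexagons.  With S = 0 every D is 0 and embers never leave the cell.
    """
    e_max = int(_round(f * params.ember_creation_rate))
    count = int(rng.integers(0, e_max + 1))
    embers = []
    for _ in range(count):
        d = int(_round(rng.uniform(0.0, s * params.ember_max_distance)))
        embers.append(Ember(CellIndex(*cell), assigned_distance=d))
    return embers


def move_ember(
    ember: Ember,
    g,  # CellMap gradient
    barrier: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
) -> CellIndex | None:
    """Fly one ember to its landing cell; ``None`` means it left the grid.

    The flight alternates wind steps with random steps until the assigned
    distance is reached.  A wind step is a run of up to
    ``ember_step_length_wind`` hexagons climbing the wind gradient (each
    hexagon re-evaluating the local uphill neighbor); a random step is a
    straight run of up to ``ember_step_length_random`` hexagons in one
    uniformly drawn hex direction.  Every hexagon moved increments
    ``traveled``, stopping exactly at the assigned distance.  Entering a
    barrier cell is refused and ends the flight at the current cell; leaving
    the grid extinguishes the ember (gradient moves only ever target
    in-bounds cells, so only random steps can exit).
    """
    grid = g.grid
    lw = params.ember_step_length_wind
    lr = params.ember_step_length_random
    cycle = lw + lr
    pos = CellIndex(*ember.position)
    if cycle == 0:
        ember.position = pos
        return pos
    rand_dir = -1
    while ember.traveled < ember.assigned_distance:
        cyc_pos = ember.traveled % cycle
        if cyc_pos < lw:
            target = uphill_neighbor(g, pos, rng)
        else:
            if cyc_pos == lw or rand_dir < 0:
                rand_dir = int(rng.integers(6))  # one direction per random step
            r, c = pos
            offsets = (
                hexgrid._OFFSETS_ODD if r % 2 else hexgrid._OFFSETS_EVEN
            )
            dr, dc = offsets[rand_dir]
            tr, tc = r + dr, c + dc
            if not (0 <= tr < grid.rows and 0 <= tc < grid.cols):
                return None  # extinguished off-grid
            target = CellIndex(tr, tc)
        if barrier[target.row, target.col]:
            break  # barriers repel embers: flight ends short
        pos = target
        ember.traveled += 1
    ember.position = pos
    return pos


def land_ember(
    cell: CellIndex,
    state: SimState,
    f: float,
    beta: float,
    rng: np.random.Generator,
) -> CellIndex | None:
    """Resolve one landed ember; returns the ignited cell or ``None``.

    An unburned landing cell ignites with probability P_flammability(F, beta);
    burning and burned cells are unaffected.  The ember is consumed either
    way.  The ignition is returned uncommitted, like contagion ignitions.
    """
    r, c = cell
    if state.state[r, c] != UNBURNED:
        return None
    if rng.random() < p_flammability(f, beta):
        return CellIndex(r, c)
    return None


def advance_burning(state: SimState, params: SimParams) -> SimState:
    """Decrement every burning cell's remaining iterates; retire at zero.

    A cell ignited in iteration k (committed at its end with the full
    ``iterates_to_burn_completely`` budget) is an active fire source during
    iterations k+1 ... k+budget and BURNED thereafter.  BURNED is absorbing.
    """
    burning = state.state == BURNING
    state.remaining[burning] -= 1
    done = burning & (state.remaining <= 0)
    state.state[done] = BURNED
    state.remaining[done] = 0
    return state


# ---------------------------------------------------------------------------
# vectorized engine

# direction offset tables indexed [parity, direction], E W NE NW SE SW
_DR = np.array(
    [[dr for dr, _ in hexgrid._OFFSETS_EVEN], [dr for dr, _ in hexgrid._OFFSETS_ODD]],
    dtype=np.int64,
)
_DC = np.array(
    [[dc for _, dc in hexgrid._OFFSETS_EVEN], [dc for _, dc in hexgrid._OFFSETS_ODD]],
    dtype=np.int64,
)


@dataclass
class BurnOutcome:
    """Result of one simulation run."""

    grid: GridSpec
    state: np.ndarray  # final per-cell state (uint8)
    steps_run: int
    seed: int | None
    log: pd.DataFrame  # per-step burning/burned/ember/ignition counts
    snapshots: list[np.ndarray] | None = None

    @property
    def burned_mask(self) -> np.ndarray:
        """Cells burned or still burning at the end of the run."""
        return self.state != UNBURNED

    @property
    def burned_cells(self) -> int:
        return int(np.count_nonzero(self.state != UNBURNED))


class Simulation:
    """A runnable simulation: landscape + schedules + parameters.

    Precomputes the neighbor and gradient lookup tables once so repeated
    runs (replicates) stay fast.  ``run`` never mutates the landscape passed
    in; fuel breaks act on a private copy of the flammability layer.
    """

    def __init__(
        self,
        maps: LandscapeMaps,
        schedules: Schedules | None = None,
        params: SimParams | None = None,
    ) -> None:
        self.maps = maps
        self.schedules = schedules or Schedules()
        self.params = params or SimParams()
        self.schedules.ignitions.check_bounds(maps.grid)
        self.schedules.fuel_breaks.check_bounds(maps.grid)
        nr, nc, valid = hexgrid.neighbor_table(maps.grid)
        self._nr, self._nc, self._valid = nr, nc, valid
        g = maps.wind_gradient
        gv = g[nr, nc]
        gv[~valid] = -np.inf
        self._gvals = gv

    # -- ember flight, vectorized across all embers of one iteration --------
    def _fly(
        self,
        r: np.ndarray,
        c: np.ndarray,
        dist: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
        params = self.params
        grid = self.maps.grid
        barrier = self.maps.barrier
        g = self.maps.wind_gradient
        lw = params.ember_step_length_wind
        lr = params.ember_step_length_random
        cycle = lw + lr
        n = len(r)
        traveled = np.zeros(n, dtype=np.int64)
        alive = np.ones(n, dtype=bool)  # not extinguished off-grid
        moving = dist > 0
        rdir = np.full(n, -1, dtype=np.int64)  # current random-step direction
        if cycle == 0:
            moving[:] = False
        while True:
            act = np.flatnonzero(alive & moving & (traveled < dist))
            if len(act) == 0:
                break
            cyc_pos = traveled[act] % cycle
            in_wind = cyc_pos < lw
            wi = act[in_wind]
            if len(wi):
                gv = self._gvals[r[wi], c[wi], :]
                here = g[r[wi], c[wi]]
                vmax = gv.max(axis=1)
                better = vmax > here
                choose = np.where(
                    better[:, None], gv == vmax[:, None], self._valid[r[wi], c[wi], :]
                )
                keys = np.where(choose, rng.random(choose.shape), -1.0)
                pick = keys.argmax(axis=1)
                tr = self._nr[r[wi], c[wi], pick]
                tc = self._nc[r[wi], c[wi], pick]
                blocked = barrier[tr, tc]
                moving[wi[blocked]] = False
                ok = ~blocked
                oki = wi[ok]
                r[oki] = tr[ok]
                c[oki] = tc[ok]
                traveled[oki] += 1
            ri = act[~in_wind]
            if len(ri):
                # a random step is a straight run: draw one direction at the
                # start of each run and hold it for up to L_r hexagons
                fresh = (cyc_pos[~in_wind] == lw) | (rdir[ri] < 0)
                if fresh.any():
                    rdir[ri[fresh]] = rng.integers(0, 6, size=int(fresh.sum()))
                d6 = rdir[ri]
                parity = r[ri] % 2
                tr = r[ri] + _DR[parity, d6]
                tc = c[ri] + _DC[parity, d6]
                off = (tr < 0) | (tr >= grid.rows) | (tc < 0) | (tc >= grid.cols)
                alive[ri[off]] = False
                inb = ~off
                blocked = np.zeros(len(ri), dtype=bool)
                blocked[inb] = barrier[tr[inb], tc[inb]]
                moving[ri[blocked]] = False
                ok = inb & ~blocked
                oki = ri[ok]
                r[oki] = tr[ok]
                c[oki] = tc[ok]
                traveled[oki] += 1
        return r[alive], c[alive]

    def _spot_iteration(
        self, state: SimState, rng: np.random.Generator
    ) -> tuple[np.ndarray, int]:
        """Emit, fly, and land all embers for one iteration.

        Reads the iteration-entry state; returns (uncommitted ignition mask,
        number of embers emitted).
        """
        params = self.params
        maps = self.maps
        ignitions = np.zeros(state.grid.shape, dtype=bool)
        src = np.flatnonzero(state.burning.ravel())  # row-major source order
        if len(src) == 0 or params.ember_creation_rate == 0:
            return ignitions, 0
        f_src = maps.flammability.ravel()[src]
        e_max = _round(f_src * params.ember_creation_rate)
        counts = rng.integers(0, e_max + 1)
        total = int(counts.sum())
        if total == 0:
            return ignitions, 0
        src_rep = np.repeat(src, counts)
        s_rep = maps.wind_speed.ravel()[src_rep]
        dist = _round(
            rng.uniform(0.0, 1.0, size=total) * (s_rep * params.ember_max_distance)
        )
        r = (src_rep // state.grid.cols).astype(np.int64)
        c = (src_rep % state.grid.cols).astype(np.int64)
        lr_, lc_ = self._fly(r, c, dist, rng)
        if len(lr_) == 0:
            return ignitions, total
        unburned = state.state[lr_, lc_] == UNBURNED
        lr_, lc_ = lr_[unburned], lc_[unburned]
        if len(lr_) == 0:
            return ignitions, total
        p = p_flammability(
            maps.flammability[lr_, lc_], params.flammability_exponent
        )
        hit = rng.random(len(lr_)) < p
        ignitions[lr_[hit], lc_[hit]] = True
        return ignitions, total

    def _iteration(self, state: SimState, rng: np.random.Generator) -> dict:
        """One burn iteration: contagion, spotting, progression, commit."""
        params = self.params
        contagion = contagion_iteration(state, self.maps, params, rng)
        spotting, n_embers = self._spot_iteration(state, rng)
        advance_burning(state, params)
        new = (contagion | spotting) & (state.state == UNBURNED)
        state.state[new] = BURNING
        state.remaining[new] = params.iterates_to_burn_completely
        return {"ignitions": int(new.sum()), "embers": n_embers}

    def step(self, state: SimState, t: int, rng: np.random.Generator) -> dict:
        """Advance one model time step (scheduled events + burn iterations)."""
        params = self.params
        apply_fuel_breaks(self.maps, self.schedules.fuel_breaks, t)
        for cell in self.schedules.ignitions.cells_at(t):
            # scheduled ignitions succeed deterministically iff fuel remains
            if self.maps.flammability[cell.row, cell.col] > 0:
                state.ignite(cell, params)
        n_embers = n_ign = 0
        for i in range(params.burn_iterations_per_time_step):
            state.clock = (t, i)
            info = self._iteration(state, rng)
            n_embers += info["embers"]
            n_ign += info["ignitions"]
        state.clock = (t + 1, 0)
        return {
            "time_step": t,
            "burning": int(np.count_nonzero(state.state == BURNING)),
            "burned": int(np.count_nonzero(state.state == BURNED)),
            "embers": n_embers,
            "ignitions": n_ign,
        }

    def run(self, duration: int, seed: int | None = None) -> BurnOutcome:
        """Run the simulation for up to ``duration`` time steps.

        With ``random_fires_max > 0``, a number of fires uniform on
        [random_fires_min, random_fires_max] is set at distinct random
        fuel-bearing cells at step 0.  With ``early_termination``, the run
        stops at the first step boundary with no actively burning cells.
        Fully reproducible given ``seed``.
        """
        if duration < 1:
            raise ValueError("duration must be >= 1")
        params = self.params
        maps_orig = self.maps
        self.maps = maps_orig.copy()  # fuel breaks must not leak across runs
        try:
            rng = np.random.default_rng(seed)
            state = SimState.initial(self.maps.grid)
            extra: list[CellIndex] = []
            if params.random_fires_max > 0:
                n_fires = int(
                    rng.integers(params.random_fires_min, params.random_fires_max + 1)
                )
                ignitable = np.flatnonzero(self.maps.flammability.ravel() > 0)
                if n_fires > 0 and len(ignitable) == 0:
                    raise ValueError(
                        "random fires requested but no cell has fuel (F > 0)"
                    )
                if n_fires > 0:
                    picks = rng.choice(ignitable, size=min(n_fires, len(ignitable)),
                                       replace=False)
                    cols = self.maps.grid.cols
                    extra = [CellIndex(int(p) // cols, int(p) % cols) for p in picks]
            records = []
            snapshots: list[np.ndarray] | None = (
                [] if params.output_mode == "per_step" else None
            )
            steps_run = 0
            for t in range(duration):
                if t == 0:
                    for cell in extra:
                        state.ignite(cell, params)
                rec = self.step(state, t, rng)
                records.append(rec)
                if snapshots is not None:
                    snapshots.append(state.state.copy())
                steps_run = t + 1
                if params.early_termination and rec["burning"] == 0:
                    break
            log = pd.DataFrame.from_records(
                records,
                columns=["time_step", "burning", "burned", "embers", "ignitions"],
            )
            return BurnOutcome(
                grid=self.maps.grid,
                state=state.state,
                steps_run=steps_run,
                seed=seed,
                log=log,
                snapshots=snapshots,
            )
        finally:
            self.maps = maps_orig


def time_step(
    state: SimState,
    maps: LandscapeMaps,
    schedules: Schedules,
    params: SimParams,
    rng: np.random.Generator,
    t: int | None = None,
) -> SimState:
    """Advance ``state`` by one model time step (in place; also returned).

    Applies fuel breaks and scheduled ignitions for time ``t`` (default: the
    state's own clock), then runs ``burn_iterations_per_time_step`` burn
    iterations.  Mutates ``maps.flammability`` where fuel breaks fire.
    """
    sim = Simulation(maps, schedules, params)
    sim.maps = maps  # operate on the caller's maps, per the in-place contract
    sim.step(state, state.clock[0] if t is None else t, rng)
    return state


def run_simulation(
    maps: LandscapeMaps,
    schedules: Schedules | None,
    params: SimParams,
    duration: int,
    seed: int | None = None,
) -> BurnOutcome:
    """Run one full simulation; see :meth:`Simulation.run`."""
    return Simulation(maps, schedules, params).run(duration, seed)
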