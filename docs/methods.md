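# Methods

## Model structure

The simulator is a stochastic cellular automaton on a pointy-top hexagonal
lattice, coupled with ember agents for fire spotting.  Cells are addressed
in odd-r offset coordinates (odd rows shifted half a cell right), row 0 at
the top, so the lattice maps one-to-one onto rectangular raster storage and
ESRI ASCII grids.  The y axis increases downward; a wind bearing of 180°
("due south") therefore points toward increasing row index.  Cell states
follow the machine UNBURNED → BURNING → BURNED; BURNED is absorbing.  The
lattice boundary is absorbing as well: neighbors outside the grid do not
exist, and embers that fly off the grid are extinguished.

Time is organized in user-interpreted time steps (one hour in the worked
examples), each containing `burn_iterations_per_time_step` burn iterations.
One iteration performs, in order:

1. **Contagion** — for every unburned cell with at least one burning
   neighbor, draw `R ~ U(0,1)` and ignite if
   `P_contagion = [1 − (1 − N/6)^α]·[1 − (1 − F)^β] > R`.
2. **Spotting** — every burning cell emits `U{0, …, round(F·ε)}` embers;
   each flies (see below) and, if it lands on an unburned cell, ignites it
   with probability `1 − (1 − F)^β`.
3. **Progression** — each burning cell's remaining-iterate counter
   decrements; at zero the cell becomes BURNED.
4. **Commit** — ignitions from (1) and (2) become BURNING with the full
   `iterates_to_burn_completely` budget.

The update is synchronous: steps (1) and (2) both read the state at
iteration entry, so a cell ignited in iteration *k* spreads and emits
during iterations *k*+1 … *k*+`iterates_to_burn_completely`, and the
relative order of contagion and spotting within an iteration does not
affect the distribution of outcomes (it is fixed anyway, for
reproducibility).  Scheduled events (fuel breaks, then ignitions) are
applied at the start of each time step; a scheduled ignition succeeds
deterministically iff the cell still has fuel (`F > 0`).

## Ember flight

An ember's assigned distance is `D = round(U(0, S·δ))` hexagons, so the
local relative wind speed scales the *maximum* flight range and realized
distances are uniform up to that maximum.  Flight alternates **wind steps**
and **random steps** until exactly `D` hexagons have been traversed:

* a wind step is a run of up to `ember_step_length_wind` single-hex moves,
  each to the neighbor with the highest wind-gradient potential (ties split
  uniformly; at a local maximum of the potential the move degrades to a
  uniformly random neighbor so embers cannot stall);
* a random step is a *straight* run of up to `ember_step_length_random`
  hexagons in one uniformly drawn hex direction — one direction per step,
  held for the whole run, matching the parameters' definition as step
  *lengths* in hexagons.  Treating the random step as independent per-hex
  wobbles instead would make long random steps diffusive (net displacement
  ~√L rather than ~L) and demonstrably fails to reproduce the
  parameter-study orderings: the wide-scatter variant and the hybrid
  variant lose most of their reach.

A move into a fuel-barrier cell is refused and ends the flight at the
current cell (barriers repel embers but do not block contagion, which is
why they pair with back burns); a move off the grid extinguishes the ember.
Embers resolve entirely within their emission iteration — there is no
mechanism for an ember to stay airborne across iterations.

## Wind gradients

Embers climb a scalar potential G.  From a map of wind bearings θ (degrees
clockwise from grid-north, the direction the wind blows toward) each cell
is seeded with the planar ramp `G = x·sin θ − y·cos θ` in hexagon-center
coordinates, optionally blended by hex-neighborhood mean smoothing for
spatially varying fields.  For a constant bearing this is exactly the ramp
increasing downwind; for varying fields it is one reasonable potential
among many and is documented as approximate.  Note the pointy-top lattice
has no direct north/south neighbor: under a due-south gradient the SE and
SW neighbors tie exactly and the ember zigzags south, advancing one row per
hex moved.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `burn_iterations_per_time_step` | 2 | spread iterations per model time step |
| `iterates_to_burn_completely` | 3 | iterations a cell remains an active source |
| `flammability_exponent` (β) | 2 | sensitivity of ignition to fuel F |
| `proximity_exponent` (α) | 0.5 | sensitivity of contagion to burning neighbors N |
| `ember_creation_rate` (ε) | 5 | max embers per burning cell per iteration |
| `ember_max_distance` (δ) | 10 | max ember flight, hexagons |
| `ember_step_length_wind` | 1 | hexagons per gradient-climbing step |
| `ember_step_length_random` | 1 | hexagons per straight random step |

The defaults are the baseline of the checkerboard parameter study; the
variants override them one at a time (B: β=5, α=0.2; C: β=0.2, α=5;
D: δ=50; E: L_w=10; F: L_r=10; hybrid: B+D+F combined).  Optional settings
cover random ignition (a uniform count in `[random_fires_min,
random_fires_max]` of distinct fuel-bearing cells at step 0), early
termination when no cell is burning at a step boundary, and per-step
snapshot output.

## Numerical choices

* "Rounded to an integer" for ember counts and distances is
  round-half-to-even (`np.rint`).  Distances are continuous draws, so the
  convention only matters for counts whose product `F·ε` lands exactly on
  .5.
* Each run uses a single `numpy` PCG64 generator; replicate *r* of a batch
  uses `base_seed + r`.  Runs are bit-reproducible given a seed.  Draws
  occur in a fixed order (contagion candidates row-major, then ember
  counts, distances, flight, landings), which makes "2 iterations/step for
  T steps" bit-identical to "1 iteration/step for 2T steps".
* Fuel breaks act on a private copy of the flammability layer inside
  `Simulation.run`, so a landscape object can be shared across replicates.
  Breaks never extinguish already-burning cells: fuel removal affects only
  future ignition.
* `validate` treats shape mismatches as fatal and range/NaN violations as
  reportable diagnostics.

## Synthetic landscapes and what the tests show

The generators fabricate the study conditions: a checkerboard of 10×10-hex
blocks alternating flammability 1.00/0.25 on a 500×500 grid; uniform wind
speed 1 with a due-south gradient; and a smoothed-random fuel map (seed
points, hex-mean smoothing, then the concave transform `v^(1/k)`, k>1, to
exaggerate large values).  The checkerboard's top-center ignition falls on
the boundary between two blocks when the column count is even; the tie is
broken toward the high-flammability block, since a single low-fuel ignition
cell fizzles in a substantial fraction of replicates and the parameter
study is about spread, not ignition success.  The exact smoothing recipe
behind any particular real-landscape map is not reproducible cell-for-cell;
the generator aims for plausible patchiness, not replication.

These are deliberately stylized inputs.  Passing the validation suite shows
the mechanisms behave as specified (formula exactness, oracle-level
contagion statistics, absolute blocking, ordering of variant effects); it
does not show that any parameterization forecasts real fire behavior, which
would require calibrated flammability/ROS and wind surfaces.

## Validation problem sizes

The ordering study runs 30 replicates per variant of the full 500×500,
24-step setup and tests each directional claim by one-sided Mann-Whitney at
p < 0.01 (all observed p < 1e-4).  The contagion oracle uses a 7-cell
flower with heterogeneous fuels, exact Poisson-binomial enumeration over
all 2⁶ neighbor outcomes, and 10⁵ simulated iterations (5×10⁴ in the
acceptance script).  The blocking check uses a 12-row bare band against
δ = 10 over 50 replicates.  The coupling study uses a 40×40 landscape,
a 30-burn library, and 60-year toy-population runs.

## The coupled population model

The disturbance interface is file-based: a library of final burn maps (with
seed and size metadata) feeds a habitat-based model.  `apply_burn` zeroes
habitat quality throughout a burn; `remove_agents` drops individuals inside
it — a worst-case in which animals cannot escape.  The demographic model is
intentionally minimal: carrying capacity K proportional to summed habitat
quality, Ricker growth with Poisson demographic noise, initialized at K,
disturbance applied before year 1 with removals proportional to habitat
lost.  It preserves the coupling's experimental design (disturbance at year
0, steady-state comparison, inflated variability under fire) and makes no
attempt at territory economics, stage structure, dispersal, or any
particular species' demography.

## Known limitations

* No topography, moisture, or atmospheric coupling; a rate-of-spread map
  can stand in for flammability if those effects are pre-composited.
* The wind-gradient potential from spatially varying direction maps is
  heuristic (not curl-free); dynamic wind requires swapping maps per step.
* Ember count/distance laws are uniform-with-maximum by construction; the
  model fixes only the maxima, so other laws (e.g., Poisson counts) are
  plausible drop-in replacements.
* Lattice topology, not cell-by-cell identity, is the level at which this
  implementation matches other hexagonal fire automata: a different hexagon
  orientation or indexing yields statistically equivalent, not identical,
  outputs.
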