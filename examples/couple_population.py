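"""Fire as a disturbance generator for a coupled population model.

Burn realizations are collected into a library; each population replicate
draws one burn, zeroes habitat quality throughout the burned area, removes
the individuals living there, and then runs 50 years of stochastic logistic
dynamics whose carrying capacity tracks the remaining habitat.  Comparing
against undisturbed runs shows the two signatures of fire impact: a lower
(burn-size-dependent) equilibrium and dramatically inflated variability.
"""

import numpy as np

from hexfire import CellMap, GridSpec, SimParams, gen_smoothed_random, gen_uniform_wind
from hexfire.coupling import build_library, toy_population_run
from hexfire.experiments import Scenario
from hexfire.landscape import LandscapeMaps, Schedules
from hexfire.windfield import build_gradient

ROWS = COLS = 40


def builder():
    flam = gen_smoothed_random(ROWS, COLS, 25, 8, 3.0, seed=77)
    speed, dirs = gen_uniform_wind(ROWS, COLS, 1.0, 180.0)
    return (
        LandscapeMaps.from_maps(flam, speed, build_gradient(dirs)),
        Schedules(),
    )


params = SimParams(
    burn_iterations_per_time_step=1,
    iterates_to_burn_completely=5,
    random_fires_min=1,
    random_fires_max=1,
    early_termination=True,
)
library = build_library(
    Scenario("fires", params, builder, duration=200),
    quota=25, min_size=40, base_seed=3,
)
print(f"disturbance library: {len(library)} burns, "
      f"{min(library.sizes)}-{max(library.sizes)} hexagons")

habitat = CellMap(GridSpec(ROWS, COLS), np.ones((ROWS, COLS)))  # K = 1600
rng = np.random.default_rng(0)
undisturbed = np.array(
    [toy_population_run(habitat, None, years=50, seed=100 + i) for i in range(20)]
)
disturbed = np.array(
    [
        toy_population_run(habitat, library.draw(rng), years=50, seed=200 + i)
        for i in range(40)
    ]
)

print(f"undisturbed: mean final {undisturbed[:, -1].mean():6.0f}, "
      f"minimum over years 10-50 {undisturbed[:, 10:].min():6.0f}")
print(f"with fire:   mean final {disturbed[:, -1].mean():6.0f}, "
      f"minimum over years 10-50 {disturbed[:, 10:].min():6.0f}")
print(f"final-size spread (sd): {undisturbed[:, -1].std():.0f} undisturbed "
      f"vs {disturbed[:, -1].std():.0f} with fire")
print(
    "\nFire lowers the population in proportion to the habitat burned and"
    "\nmakes outcomes far more variable - the worst years are much worse."
)
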