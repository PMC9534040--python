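"""Core fire dynamics: spread probabilities, embers, burn progression, runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hexfire.fire_engine import (
    BURNED,
    BURNING,
    UNBURNED,
    Ember,
    SimParams,
    SimState,
    Simulation,
    advance_burning,
    contagion_iteration,
    emit_embers,
    land_ember,
    move_ember,
    p_contagion,
    p_flammability,
    p_proximity,
    run_simulation,
)
from hexfire.hexgrid import CellIndex, CellMap, GridSpec
from hexfire.landscape import IgnitionSchedule, Schedules
from hexfire.windfield import build_gradient

from conftest import south_wind_maps


def hex_distance(a: CellIndex, b: CellIndex) -> int:
    """Hex-lattice distance via cube coordinates (odd-r offset)."""

    def cube(cell):
        r, c = cell
        x = c - (r - (r & 1)) // 2
        z = r
        return x, -x - z, z

    ax, ay, az = cube(a)
    bx, by, bz = cube(b)
    return (abs(ax - bx) + abs(ay - by) + abs(az - bz)) // 2


def burning_state(maps, cells, remaining=3):
    state = SimState.initial(maps.grid)
    for r, c in cells:
        state.state[r, c] = BURNING
        state.remaining[r, c] = remaining
    return state


class TestSpreadProbabilities:
    def test_proximity_endpoints(self):
        for alpha in (0.2, 0.5, 1.0, 2.0, 5.0):
            assert p_proximity(0, alpha) == 0.0
            assert p_proximity(6, alpha) == pytest.approx(1.0)

    def test_proximity_reference_value(self):
        # N=3, alpha=0.5: 1 - (1/2)**0.5
        assert p_proximity(3, 0.5) == pytest.approx(0.2928932188134524, abs=1e-12)

    def test_flammability_endpoints_and_reference(self):
        assert p_flammability(0.0, 3.0) == 0.0
        assert p_flammability(1.0, 0.7) == 1.0
        # the low-flammability checkerboard block under the baseline exponent
        assert p_flammability(0.25, 2.0) == pytest.approx(0.4375, abs=1e-12)

    def test_contagion_product_and_annihilators(self):
        assert p_contagion(6, 1.0, 0.5, 2.0) == pytest.approx(1.0)
        assert p_contagion(0, 1.0, 0.5, 2.0) == 0.0
        assert p_contagion(3, 0.0, 0.5, 2.0) == 0.0
        assert p_contagion(3, 0.25, 0.5, 2.0) == pytest.approx(
            0.2928932188134524 * 0.4375, abs=1e-12
        )

    @settings(deadline=None, max_examples=60)
    @given(
        st.integers(0, 5),
        st.floats(0.01, 0.99),
        st.floats(0.1, 8.0),
    )
    def test_monotone_in_count_and_fuel(self, n, f, expo):
        assert p_proximity(n + 1, expo) > p_proximity(n, expo)
        assert p_flammability(min(f + 0.01, 1.0), expo) > p_flammability(f, expo)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            p_proximity(7, 1.0)
        with pytest.raises(ValueError):
            p_proximity(3, 0.0)
        with pytest.raises(ValueError):
            p_flammability(1.2, 1.0)


class TestContagionIteration:
    def test_single_burning_cell_neighbor_ignition_rate(self):
        # per-neighbor rate with N=1, F=1, alpha=0.5: 1 - (5/6)**0.5
        maps = south_wind_maps(5, 5)
        params = SimParams()
        state = burning_state(maps, [(2, 2)])
        rng = np.random.default_rng(7)
        trials = 20_000
        hits = 0
        probe = (3, 2)  # one specific neighbor of (2, 2)
        for _ in range(trials):
            ign = contagion_iteration(state, maps, params, rng)
            hits += ign[probe]
        p_true = 1.0 - (5.0 / 6.0) ** 0.5
        se = np.sqrt(p_true * (1 - p_true) / trials)
        assert abs(hits / trials - p_true) < 3 * se

    def test_no_fuel_means_no_ignitions(self):
        maps = south_wind_maps(5, 5, flammability=0.0)
        state = burning_state(maps, [(2, 2)])
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert not contagion_iteration(state, maps, SimParams(), rng).any()

    def test_does_not_commit_or_mutate_state(self):
        maps = south_wind_maps(5, 5)
        state = burning_state(maps, [(2, 2)])
        before = state.state.copy()
        contagion_iteration(state, maps, SimParams(), np.random.default_rng(1))
        assert np.array_equal(state.state, before)

    def test_burned_cells_do_not_count_as_burning(self):
        maps = south_wind_maps(5, 5)
        state = SimState.initial(maps.grid)
        state.state[2, 2] = BURNED
        assert not contagion_iteration(
            state, maps, SimParams(), np.random.default_rng(2)
        ).any()


class TestEmitEmbers:
    def test_count_bounded_by_rounded_rate(self, rng):
        params = SimParams()  # epsilon = 5
        counts = [len(emit_embers((2, 2), 1.0, 1.0, params, rng)) for _ in range(500)]
        assert max(counts) <= 5
        assert min(counts) >= 0
        assert len(set(counts)) > 3  # count actually varies over {0..5}

    def test_windless_embers_never_leave_cell(self, rng):
        params = SimParams()
        for _ in range(100):
            for e in emit_embers((1, 1), 1.0, 0.0, params, rng):
                assert e.assigned_distance == 0

    def test_distance_mean_half_of_max(self, rng):
        # D = round(U(0, 10)): mean 5.0
        params = SimParams()
        dists = []
        while len(dists) < 20_000:
            dists.extend(
                e.assigned_distance
                for e in emit_embers((0, 0), 1.0, 1.0, params, rng)
            )
        d = np.asarray(dists[:20_000], dtype=float)
        assert d.max() <= 10
        se = np.sqrt(100 / 12 / len(d))
        assert abs(d.mean() - 5.0) < 3 * se

    def test_low_fuel_caps_emission(self, rng):
        # F=0.25, epsilon=5 -> E_max = round(1.25) = 1
        counts = [
            len(emit_embers((0, 0), 0.25, 1.0, SimParams(), rng)) for _ in range(300)
        ]
        assert max(counts) == 1


class TestMoveEmber:
    def test_zero_distance_lands_at_source(self, rng, south_maps_30x30):
        g = CellMap(south_maps_30x30.grid, south_maps_30x30.wind_gradient)
        e = Ember(CellIndex(5, 5), assigned_distance=0)
        barrier = south_maps_30x30.barrier
        assert move_ember(e, g, barrier, SimParams(), rng) == CellIndex(5, 5)

    def test_pure_wind_flight_tracks_gradient_exactly(self, rng, south_maps_30x30):
        # wind-tracking variant geometry: a 10-hex wind step covers the whole
        # assigned distance, landing exactly 10 rows downwind
        g = CellMap(south_maps_30x30.grid, south_maps_30x30.wind_gradient)
        params = SimParams(ember_step_length_wind=10, ember_step_length_random=1)
        for _ in range(20):
            e = Ember(CellIndex(3, 15), assigned_distance=10)
            land = move_ember(e, g, south_maps_30x30.barrier, params, rng)
            assert land.row == 13

    def test_random_step_is_one_straight_run(self, rng, south_maps_30x30):
        # with no wind phase, a 10-hex random step goes straight: the landing
        # cell is exactly 10 hexes from the source
        grid = south_maps_30x30.grid
        g = CellMap(grid, np.zeros(grid.shape))  # flat gradient irrelevant
        params = SimParams(ember_step_length_wind=0, ember_step_length_random=10)
        src = CellIndex(15, 15)
        for _ in range(50):
            e = Ember(src, assigned_distance=10)
            land = move_ember(e, g, south_maps_30x30.barrier, params, rng)
            if land is not None:  # some straight runs exit the 30x30 grid
                assert hex_distance(src, land) == 10

    def test_barrier_ring_contains_embers(self, rng):
        maps = south_wind_maps(31, 31)
        src = CellIndex(15, 15)
        for r in range(31):
            for c in range(31):
                if hex_distance(src, CellIndex(r, c)) == 3:
                    maps.barrier[r, c] = True
        g = CellMap(maps.grid, maps.wind_gradient)
        for _ in range(200):
            e = Ember(src, assigned_distance=10)
            land = move_ember(e, g, maps.barrier, SimParams(), rng)
            assert land is not None
            assert hex_distance(src, land) <= 3

    def test_never_travels_beyond_assigned_distance(self, rng, south_maps_30x30):
        g = CellMap(south_maps_30x30.grid, south_maps_30x30.wind_gradient)
        for d in (1, 4, 7, 10):
            e = Ember(CellIndex(14, 14), assigned_distance=d)
            move_ember(e, g, south_maps_30x30.barrier, SimParams(), rng)
            assert e.traveled <= d <= SimParams().ember_max_distance


class TestLandEmber:
    def test_certain_and_impossible_ignition(self, rng, south_maps_30x30):
        state = SimState.initial(south_maps_30x30.grid)
        assert land_ember(CellIndex(2, 2), state, 1.0, 2.0, rng) == CellIndex(2, 2)
        assert land_ember(CellIndex(2, 2), state, 0.0, 2.0, rng) is None

    def test_burning_cell_unaffected(self, rng, south_maps_30x30):
        state = burning_state(south_maps_30x30, [(2, 2)])
        assert land_ember(CellIndex(2, 2), state, 1.0, 2.0, rng) is None

    def test_landing_ignition_rate_matches_flammability_curve(self, rng):
        maps = south_wind_maps(3, 3)
        state = SimState.initial(maps.grid)
        trials = 20_000
        hits = sum(
            land_ember(CellIndex(1, 1), state, 0.25, 2.0, rng) is not None
            for _ in range(trials)
        )
        se = np.sqrt(0.4375 * 0.5625 / trials)
        assert abs(hits / trials - 0.4375) < 3 * se


class TestBurnProgression:
    def _lone_fire_params(self, **kw):
        return SimParams(
            burn_iterations_per_time_step=1,
            ember_creation_rate=0.0,
            early_termination=False,
            output_mode="per_step",
            **kw,
        )

    def test_three_iterates_burn_three_active_steps(self):
        maps = south_wind_maps(5, 5, flammability=0.0)
        maps.flammability[2, 2] = 1.0  # fuel only at the ignition cell
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(2, 2))]))
        params = self._lone_fire_params(iterates_to_burn_completely=3)
        out = run_simulation(maps, sched, params, duration=6, seed=0)
        burning_per_step = list(out.log["burning"])
        assert burning_per_step == [1, 1, 0, 0, 0, 0]
        # active (emitting/spreading) at entry of exactly 3 iterations:
        # the pre-retirement snapshots show BURNING for steps 0 and 1
        assert out.snapshots[0][2, 2] == BURNING
        assert out.snapshots[1][2, 2] == BURNING
        assert out.snapshots[2][2, 2] == BURNED

    def test_single_iterate_burns_one_step(self):
        maps = south_wind_maps(5, 5, flammability=0.0)
        maps.flammability[2, 2] = 1.0
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(2, 2))]))
        params = self._lone_fire_params(iterates_to_burn_completely=1)
        out = run_simulation(maps, sched, params, duration=3, seed=0)
        assert list(out.log["burning"]) == [0, 0, 0]
        assert out.snapshots[0][2, 2] == BURNED

    def test_burned_is_absorbing(self):
        maps = south_wind_maps(8, 8)
        state = SimState.initial(maps.grid)
        state.state[3, 3] = BURNED
        params = SimParams()
        advance_burning(state, params)
        assert state.state[3, 3] == BURNED
        # surround with fire; the burned cell must never reignite
        state.state[3, 4] = BURNING
        state.remaining[3, 4] = 3
        rng = np.random.default_rng(0)
        ign = contagion_iteration(state, maps, params, rng)
        assert not ign[3, 3]


class TestTimeStepAndRun:
    def test_no_fire_no_events_is_fixed_point(self):
        maps = south_wind_maps(10, 10)
        out = run_simulation(maps, None, SimParams(), duration=5, seed=3)
        assert out.burned_cells == 0

    def test_iteration_count_equivalence(self):
        """2 iterations/step over T steps == 1 iteration/step over 2T steps."""
        maps = south_wind_maps(40, 40, flammability=0.6)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(0, 20))]))
        fast = SimParams(burn_iterations_per_time_step=2)
        slow = SimParams(burn_iterations_per_time_step=1)
        out_fast = run_simulation(maps, sched, fast, duration=6, seed=11)
        out_slow = run_simulation(maps, sched, slow, duration=12, seed=11)
        assert np.array_equal(out_fast.state, out_slow.state)

    def test_identical_seeds_bit_identical(self):
        maps = south_wind_maps(50, 50)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(0, 25))]))
        a = run_simulation(maps, sched, SimParams(), duration=8, seed=99)
        b = run_simulation(maps, sched, SimParams(), duration=8, seed=99)
        assert np.array_equal(a.state, b.state)
        assert a.log.equals(b.log)

    def test_different_seeds_differ(self):
        maps = south_wind_maps(50, 50)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(0, 25))]))
        a = run_simulation(maps, sched, SimParams(), duration=8, seed=1)
        b = run_simulation(maps, sched, SimParams(), duration=8, seed=2)
        assert not np.array_equal(a.state, b.state)

    def test_burned_area_non_decreasing(self):
        maps = south_wind_maps(40, 40)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(0, 20))]))
        params = SimParams(output_mode="per_step")
        out = run_simulation(maps, sched, params, duration=10, seed=5)
        areas = [(s != UNBURNED).sum() for s in out.snapshots]
        assert all(b >= a for a, b in zip(areas, areas[1:]))

    def test_state_machine_transitions_legal(self):
        maps = south_wind_maps(30, 30)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(0, 15))]))
        out = run_simulation(
            maps, sched, SimParams(output_mode="per_step"), duration=8, seed=17
        )
        prev = np.full(maps.grid.shape, UNBURNED, dtype=np.uint8)
        for snap in out.snapshots:
            assert not ((prev == BURNED) & (snap != BURNED)).any()
            assert not ((prev == BURNING) & (snap == UNBURNED)).any()
            prev = snap

    def test_no_fuel_suppresses_scheduled_ignition_and_terminates(self):
        maps = south_wind_maps(10, 10, flammability=0.0)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(5, 5))]))
        params = SimParams(early_termination=True)
        out = run_simulation(maps, sched, params, duration=24, seed=0)
        assert out.burned_cells == 0
        assert out.steps_run == 1

    def test_random_fires_ignite_requested_count(self):
        maps = south_wind_maps(20, 20)
        params = SimParams(
            random_fires_min=2,
            random_fires_max=2,
            ember_creation_rate=0.0,
            flammability_exponent=2.0,
            output_mode="per_step",
        )
        # make contagion impossible so only the random ignitions appear
        maps.flammability[:] = 0.0
        maps.flammability[5, 5] = 1.0
        maps.flammability[10, 10] = 1.0
        maps.flammability[15, 15] = 1.0
        out = run_simulation(maps, None, params, duration=1, seed=21)
        assert (out.snapshots[0] != UNBURNED).sum() == 2

    def test_random_fires_without_fuel_error(self):
        maps = south_wind_maps(5, 5, flammability=0.0)
        params = SimParams(random_fires_min=1, random_fires_max=1)
        with pytest.raises(ValueError, match="no cell has fuel"):
            run_simulation(maps, None, params, duration=2, seed=0)

    def test_run_does_not_mutate_caller_maps(self):
        from hexfire.landscape import FuelBreakSchedule

        maps = south_wind_maps(10, 10)
        sched = Schedules(
            ignitions=IgnitionSchedule([(0, CellIndex(0, 5))]),
            fuel_breaks=FuelBreakSchedule([(0, CellIndex(3, 3))]),
        )
        before = maps.flammability.copy()
        run_simulation(maps, sched, SimParams(), duration=3, seed=1)
        assert np.array_equal(maps.flammability, before)

    def test_windless_spread_is_purely_contagious(self):
        """With S = 0 everywhere the footprint stays 6-connected around the
        ignition: embers never leave their source cell."""
        maps = south_wind_maps(30, 30, speed=0.0)
        sched = Schedules(ignitions=IgnitionSchedule([(0, CellIndex(15, 15))]))
        params = SimParams(burn_iterations_per_time_step=1, output_mode="per_step")
        out = run_simulation(maps, sched, params, duration=12, seed=2)
        # every newly burned cell must touch the previously burned set
        from hexfire.hexgrid import neighbor_count

        prev = np.zeros(maps.grid.shape, dtype=bool)
        prev[15, 15] = True
        for snap in out.snapshots:
            now = snap != UNBURNED
            fresh = now & ~prev
            touches = neighbor_count(prev) > 0
            assert (fresh <= touches).all()
            prev = now


class TestSimParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            SimParams(proximity_exponent=0.0)
        with pytest.raises(ValueError):
            SimParams(random_fires_min=3, random_fires_max=1)
        with pytest.raises(ValueError):
            SimParams(output_mode="sometimes")

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown parameter"):
            SimParams.from_dict({"ember_velocity": 3})
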