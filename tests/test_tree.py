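"""Murray's-law tree, exact flow solver and embolus transport physics."""

import math

import numpy as np
import pytest

from airemboli.dissolution import GasParams
from airemboli.tree import (
    MURRAY_RATIO,
    EmbolusState,
    ObstructionSeries,
    SimParams,
    Simulation,
    build_tree,
    contact_area,
    is_lodged,
    route_at_bifurcation,
    run_ensemble,
    run_simulation,
    solve_flow,
    vessel_resistance,
)
from conftest import dense_pressure_solve


class TestGeometry:
    def test_terminal_count_19_generations(self):
        assert build_tree(2.6, 19).n_terminals == 524_288

    def test_murray_halving(self):
        tree = build_tree(3.0, 5)
        assert tree.diameter(1) * 1e3 == pytest.approx(3.0 * 2 ** (-1 / 3), abs=5e-4)
        assert tree.diameter(1) * 1e3 == pytest.approx(2.381, abs=1e-3)

    def test_20_generation_variant_reaches_26um_terminals(self):
        tree = build_tree(2.6, 20)
        assert tree.diameter(20) * 1e6 == pytest.approx(26.0, abs=0.5)

    def test_resource_guard(self):
        with pytest.raises(ValueError):
            build_tree(3.0, 25)


class TestResistance:
    def test_d4_law(self):
        r1 = vessel_resistance(1e-3, 2e-2, 3.5e-3)
        assert vessel_resistance(0.5e-3, 2e-2, 3.5e-3) == pytest.approx(16 * r1)

    def test_length_linearity(self):
        r1 = vessel_resistance(1e-3, 2e-2, 3.5e-3)
        assert vessel_resistance(1e-3, 4e-2, 3.5e-3) == pytest.approx(2 * r1)

    def test_reference_value(self):
        assert vessel_resistance(1e-3, 2e-2, 3.5e-3) == pytest.approx(2.852e9, rel=1e-3)

    def test_rejects_degenerate(self):
        with pytest.raises(ValueError):
            vessel_resistance(0.0, 1e-2, 3.5e-3)


class TestFlowSolve:
    def test_unobstructed_terminals_share_flow_equally(self, small_tree):
        fs = solve_flow(small_tree)
        q_root = fs.root_flow()
        g = small_tree.generations
        for i in (0, 17, 63):
            assert fs.flow((g, i)) == pytest.approx(q_root / 2**g, rel=1e-12)

    def test_blocked_daughter_diverts_all_flow(self, small_tree):
        fs = solve_flow(small_tree, {(1, 0)})
        assert fs.flow((1, 0)) == 0.0
        assert fs.flow((1, 1)) == pytest.approx(fs.root_flow(), rel=1e-12)

    def test_matches_dense_linear_system_oracle(self, small_tree, rng):
        vessels = [(g, i) for g in range(1, 7) for i in range(2**g)]
        for _ in range(5):
            picks = rng.choice(len(vessels), size=7, replace=False)
            blocked = frozenset(vessels[int(k)] for k in picks)
            fs = solve_flow(small_tree, blocked)
            oracle = dense_pressure_solve(small_tree, blocked)
            p_ref = small_tree.input_pressure_pa
            for v in fs._mat:
                if v in blocked:
                    continue
                assert fs.downstream_pressure(v) == pytest.approx(
                    oracle[v], abs=1e-8 * p_ref
                )

    def test_flow_conservation_under_random_blockage(self, rng):
        tree = build_tree(2.8, 8)
        vessels = [(g, i) for g in range(1, 9) for i in range(2**g)]
        for _ in range(5):
            picks = rng.choice(len(vessels), size=12, replace=False)
            blocked = frozenset(vessels[int(k)] for k in picks)
            fs = solve_flow(tree, blocked)
            terminal_sum = sum(fs.flow((8, i)) for i in range(2**8))
            assert terminal_sum == pytest.approx(fs.root_flow(), rel=1e-9)

    def test_fully_blocked_root_gives_zero_flow_state(self, small_tree):
        fs = solve_flow(small_tree, {(0, 0)})
        assert fs.root_flow() == 0.0
        assert fs.obstructed_fraction() == 1.0


class TestRouting:
    def test_starved_branch_never_chosen(self, rng):
        assert all(
            route_at_bifurcation(1.0, 0.0, rng) == "left" for _ in range(100)
        )

    def test_both_dry_halts(self, rng):
        assert route_at_bifurcation(0.0, 0.0, rng) is None

    @pytest.mark.parametrize("qs, p_left", [((1.0, 1.0), 0.5), ((3.0, 1.0), 0.75)])
    def test_empirical_frequency_matches_flow_ratio(self, qs, p_left, rng):
        n = 10_000
        lefts = sum(route_at_bifurcation(*qs, rng) == "left" for _ in range(n))
        sigma = math.sqrt(n * p_left * (1 - p_left))
        assert abs(lefts - n * p_left) <= 3 * sigma


class TestLodging:
    def test_fitting_sphere_touches_nowhere(self):
        r = 100e-6
        v_sphere = (4 / 3) * math.pi * r**3
        assert contact_area(v_sphere, r) == 0.0

    def test_double_volume_contact_area(self):
        r = 50e-6
        v = 2 * (4 / 3) * math.pi * r**3
        assert contact_area(v, r) == pytest.approx((8 / 3) * math.pi * r**2, rel=1e-12)

    def test_contact_area_increases_with_volume(self):
        r = 20e-6
        vs = np.linspace(1.1, 5.0, 20) * (4 / 3) * math.pi * r**3
        areas = [contact_area(v, r) for v in vs]
        assert all(b > a for a, b in zip(areas, areas[1:]))

    def test_contact_length_threshold(self):
        """r = 13 um, dp = 1000 Pa, K = 10 N/m^2: lodges iff the cylindrical
        contact length reaches dp*r/(2K) = 0.65 mm."""
        r = 13e-6
        l_crit = 1000.0 * r / (2 * 10.0)
        v_sphere = (4 / 3) * math.pi * r**3
        just_under = v_sphere + math.pi * r * r * (0.99 * l_crit)
        just_over = v_sphere + math.pi * r * r * (1.01 * l_crit)
        assert not is_lodged(just_under, r, 1000.0, 10.0)
        assert is_lodged(just_over, r, 1000.0, 10.0)

    def test_no_pressure_differential_holds_deformed_bubble(self):
        r = 13e-6
        v = 3 * (4 / 3) * math.pi * r**3
        assert is_lodged(v, r, 0.0, 10.0)

    def test_undeformed_bubble_never_lodges(self):
        r = 100e-6
        v = 0.5 * (4 / 3) * math.pi * r**3
        assert not is_lodged(v, r, 1e6, 10.0)


class TestStep:
    def test_no_emboli_only_time_advances(self, small_tree):
        sim = Simulation(small_tree, SimParams())
        sim.step()
        assert sim.time == pytest.approx(0.1)
        assert sim.obstructed_fraction() == 0.0 and sim.emboli == []

    def test_small_bubble_traverses_and_settles_without_lodging(self):
        tree = build_tree(2.6, 19)   # terminals ~32 um
        sim = Simulation(tree, SimParams(radius_noise_rel_sd=0.0),
                         rng=np.random.default_rng(3))
        sim.inject(20.0, noisy=False)
        for _ in range(40):
            sim.step()
            assert sim.obstructed_fraction() == 0.0
        assert sim.emboli == [] and len(sim.settled) == 1
        assert sim.settled[0].vessel[0] == tree.generations

    def test_giant_bubble_lodges_shallow_and_obstructs(self):
        """A 3.5 mm bubble in a 2.6 mm MCA deforms from the root onward but
        the 100 mmHg head overwhelms stiction there; it lodges within the
        first several generations and knocks out a visible territory."""
        tree = build_tree(2.6, 19)
        sim = Simulation(tree, SimParams(radius_noise_rel_sd=0.0),
                         rng=np.random.default_rng(5))
        sim.inject(3500.0, noisy=False)
        for _ in range(100):
            sim.step()
            if any(e.lodged for e in sim.emboli):
                break
        lodged = [e for e in sim.emboli if e.lodged]
        assert lodged, "giant bubble should lodge"
        assert lodged[0].vessel[0] <= 9
        assert sim.obstructed_fraction() >= 2.0**-9

    def test_larger_bubbles_lodge_at_shallower_generations(self):
        tree = build_tree(2.6, 19)
        depths = {}
        for d_um in (3500.0, 1000.0, 500.0, 200.0):
            sim = Simulation(tree, SimParams(radius_noise_rel_sd=0.0),
                             rng=np.random.default_rng(11))
            sim.inject(d_um, noisy=False)
            for _ in range(400):
                sim.step()
                if any(e.lodged for e in sim.emboli):
                    break
            lodged = [e for e in sim.emboli if e.lodged]
            depths[d_um] = lodged[0].vessel[0] if lodged else tree.generations + 1
        assert depths[3500.0] <= depths[1000.0] <= depths[500.0] <= depths[200.0]

    def test_lodged_bubble_remobilises_as_it_shrinks(self):
        """Accelerated dissolution frees a lodged bubble, and the freed
        territory recovers perfusion."""
        tree = build_tree(2.6, 12)
        # strong undersaturation + fast diffusion so the whole cycle fits in
        # a few hundred seconds of model time
        fast_gas = GasParams(diffusivity=1e-7, saturation_fraction=0.0)
        sim = Simulation(tree, SimParams(radius_noise_rel_sd=0.0), fast_gas,
                         rng=np.random.default_rng(7))
        sim.inject(600.0, noisy=False)
        for _ in range(50):
            sim.step()
            if any(e.lodged for e in sim.emboli):
                break
        assert any(e.lodged for e in sim.emboli)
        peak = sim.obstructed_fraction()
        for _ in range(3000):
            sim.step()
            if not sim.emboli:
                break
        assert sim.emboli == []
        assert sim.obstructed_fraction() < peak


class TestRuns:
    def test_empty_schedule_stays_clear(self, small_tree):
        series = run_simulation([], small_tree, SimParams(), t_end=5.0)
        assert np.all(series.mean_percent == 0.0)

    def test_same_seed_bit_identical(self, small_tree):
        sched = [(0.0, 400.0), (1.0, 700.0)]
        a = run_simulation(sched, small_tree, SimParams(),
                           rng=np.random.default_rng(42), t_end=10.0)
        b = run_simulation(sched, small_tree, SimParams(),
                           rng=np.random.default_rng(42), t_end=10.0)
        assert np.array_equal(a.mean_percent, b.mean_percent)

    def test_ensemble_ci_brackets_mean(self, small_tree):
        sched = [(0.0, 500.0), (2.0, 800.0)]
        series = run_ensemble(sched, small_tree,
                              SimParams(ensemble_size=8, rng_seed=1), t_end=15.0)
        assert np.all(series.ci_low <= series.mean_percent + 1e-12)
        assert np.all(series.mean_percent <= series.ci_high + 1e-12)

    def test_unambiguous_run_has_zero_ci_width(self, small_tree):
        """A bubble that can never lodge leaves obstruction at exactly zero
        in every member, so the percentile band collapses."""
        series = run_ensemble(
            [(0.0, 30.0)], small_tree,
            SimParams(ensemble_size=4, radius_noise_rel_sd=0.0, rng_seed=2),
            t_end=5.0,
        )
        assert np.all(series.ci_high - series.ci_low == 0.0)

    def test_ensemble_reproducible(self, small_tree):
        sched = [(0.0, 600.0)]
        p = SimParams(ensemble_size=4, rng_seed=9)
        a = run_ensemble(sched, small_tree, p, t_end=8.0)
        b = run_ensemble(sched, small_tree, p, t_end=8.0)
        assert np.array_equal(a.mean_percent, b.mean_percent)
        assert np.array_equal(a.ci_high, b.ci_high)


class TestObstructionSeries:
    def test_invariant_enforced(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            ObstructionSeries(t, np.array([1.0, 1.0]), np.array([2.0, 0.0]),
                              np.array([3.0, 3.0]))
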