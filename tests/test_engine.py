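import numpy as np
import pytest

from conftest import make_state
from tumorca.config import (
    EngineConfig,
    PhenotypeConfig,
    RunConfig,
    SeedingConfig,
    TreatmentConfig,
)
from tumorca.engine import (
    SimConfig,
    advance_age,
    attempt_division,
    edge_reached,
    free_neighbors_moore2,
    run_simulation,
    step,
)
from tumorca.state import Cell, Geometry, LatticeState
from tumorca.treatment import NO_TREATMENT, TreatmentSchedule


class TestFreeNeighbors:
    def test_lone_cell_has_24_free_sites(self, lone_cell_state):
        free = free_neighbors_moore2(lone_cell_state, (10, 10))
        assert len(free) == 24
        assert (10, 10) not in free

    def test_fully_enclosed_cell_has_none(self, enclosed_state):
        assert free_neighbors_moore2(enclosed_state, (10, 10)) == []

    def test_corner_cell_clipped_to_8(self):
        state = make_state([(0, 0)], tau=24.0)
        free = free_neighbors_moore2(state, (0, 0))
        assert len(free) == 8  # 3x3 clipped window minus self

    def test_occupied_sites_excluded(self, lone_cell_state):
        state = make_state([(10, 10), (10, 11)], tau=24.0)
        free = free_neighbors_moore2(state, (10, 10))
        assert len(free) == 23 and (10, 11) not in free


class TestAdvanceAge:
    def test_noise_free_increment(self, rng):
        c = Cell(pos=(0, 0), tau=24.0, age=0.0, state="proliferating")
        assert advance_age(c, 1.0, 0.0, rng).age == 1.0

    def test_clamped_at_zero(self):
        class NegRng:
            def uniform(self, lo, hi):
                return lo  # always the most negative noise

        c = Cell(pos=(0, 0), tau=24.0, age=0.0, state="proliferating")
        assert advance_age(c, 1.0, 2.0, NegRng()).age == 0.0

    def test_mean_increment_unbiased(self, rng):
        incs = [
            advance_age(
                Cell(pos=(0, 0), tau=24.0, age=0.0, state="proliferating"),
                1.0, 0.1, rng,
            ).age
            for _ in range(100_000)
        ]
        assert abs(np.mean(incs) - 1.0) < 0.001


class TestAttemptDivision:
    def test_lone_cell_divides(self, lone_cell_state, rng):
        event = attempt_division(lone_cell_state, 0, 0.0, rng)
        assert event == "divided"
        assert lone_cell_state.n_cells == 2
        assert np.all(lone_cell_state.age == 0.0)  # both daughters reset
        assert lone_cell_state.n_proliferating == 2
        lone_cell_state.validate()

    def test_daughter_inherits_tau_and_lands_in_moore2(self, rng):
        state = make_state([(10, 10)], tau=17.3, age=20.0)
        attempt_division(state, 0, 0.0, rng)
        assert np.all(state.tau == 17.3)
        d = state.cell_at_index(1).pos
        assert max(abs(d[0] - 10), abs(d[1] - 10)) <= 2

    def test_enclosed_cell_becomes_quiescent(self, enclosed_state, rng):
        center = enclosed_state.index_at((10, 10))
        event = attempt_division(enclosed_state, center, 1.0, rng)
        assert event == "quiescent"
        assert enclosed_state.n_cells == 25
        assert enclosed_state.cell_at_index(center).state == "quiescent"
        # age is retained under quiescence
        assert enclosed_state.age[center] == 24.0

    def test_certain_mitotic_death_removes_cell(self, lone_cell_state, rng):
        event = attempt_division(lone_cell_state, 0, 1.0, rng)
        assert event == "mitotic_death"
        assert lone_cell_state.n_cells == 0
        assert lone_cell_state.mitotic_deaths == 1
        lone_cell_state.validate()

    def test_unripe_cell_rejected(self, rng):
        state = make_state([(10, 10)], tau=24.0, age=3.0)
        with pytest.raises(ValueError):
            attempt_division(state, 0, 0.0, rng)


class TestStep:
    def test_empty_state_just_advances_clock(self, rng):
        state = make_state(np.empty((0, 2)), tau=24.0)
        step(state, SimConfig(dt=1.0), NO_TREATMENT, rng)
        assert state.t == 1.0 and state.n_cells == 0

    def test_single_cell_divides_at_tau(self, rng):
        state = make_state([(10, 10)], tau=24.0, age=0.0)
        cfg = SimConfig(dt=1.0, age_noise_amp=0.0)
        for _ in range(24):
            step(state, cfg, NO_TREATMENT, rng)
        assert state.n_cells == 2
        assert state.births == 1

    def test_full_block_center_goes_quiescent_edges_divide(self, enclosed_state, rng):
        # 5x5 block, all ripe: the center has no free 2-Moore site
        cfg = SimConfig(dt=1.0, age_noise_amp=0.0)
        step(enclosed_state, cfg, NO_TREATMENT, rng)
        center = enclosed_state.index_at((10, 10))
        assert enclosed_state.cell_at_index(center).state == "quiescent"
        assert enclosed_state.n_cells == 25 + enclosed_state.births
        assert enclosed_state.births >= 16  # every perimeter cell can reach space
        enclosed_state.validate()

    def test_daughters_do_not_divide_same_step(self, rng):
        state = make_state([(10, 10)], tau=24.0, age=30.0)
        step(state, SimConfig(dt=1.0, age_noise_amp=0.0), NO_TREATMENT, rng)
        assert state.n_cells == 2  # one division only


class TestEdgeReached:
    def test_center_cell_far_from_edge(self):
        state = make_state([(10, 10)], tau=24.0, L=20)
        assert not edge_reached(state, 0.1)

    def test_cell_inside_margin_band(self):
        state = make_state([(1, 10)], tau=24.0, L=20)
        assert edge_reached(state, 0.1)  # row 1 < 20*0.1

    def test_boundary_of_band_is_exclusive(self):
        state = make_state([(2, 10)], tau=24.0, L=20)
        assert not edge_reached(state, 0.1)  # distance == margin

    def test_empty_state(self):
        state = make_state(np.empty((0, 2)), tau=24.0, L=20)
        assert not edge_reached(state, 0.1)


class TestRunSimulation:
    def _ten_cell_cfg(self, t_max, **eng):
        return RunConfig(
            phenotype=PhenotypeConfig(kind="homogeneous", mean_h=24.0),
            seeding=SeedingConfig(mode="sparse", n_cells=10, radius_um=1000.0,
                                  grid_side_sites=200),
            engine=EngineConfig(dt_h=1.0, t_max_h=t_max, age_noise_amp_h=0.0,
                                record_interval_h=24.0, **eng),
            seed=3,
        )

    def test_synchronous_doubling_while_space_unconstrained(self):
        # 4 full cycles with colonies below the 25-cell contact-inhibition
        # threshold: every cell divides exactly 4 times
        res = run_simulation(self._ten_cell_cfg(96.0))
        assert res.records[-1].n_total == 10 * 2**4
        assert res.stop_reason == "t_max"
        assert all(r.n_quiescent == 0 for r in res.records)

    def test_same_seed_bit_identical_records(self):
        cfg = RunConfig(
            phenotype=PhenotypeConfig(kind="normal"),
            seeding=SeedingConfig(mode="sparse", n_cells=50, radius_um=500.0,
                                  grid_side_sites=200),
            engine=EngineConfig(t_max_h=72.0, record_interval_h=8.0),
            treatment=TreatmentConfig(model="mitotic", p=0.3, schedule="constant"),
            seed=11,
        )
        a = run_simulation(cfg)
        b = run_simulation(cfg)
        assert a.records == b.records
        assert np.array_equal(a.final_doubling_times, b.final_doubling_times)

    def test_balanced_mitotic_death_holds_population_constant(self):
        # p_m = 0.5: each mitosis adds one cell or removes one, equally likely
        ratios = []
        for seed in range(20):
            cfg = RunConfig(
                phenotype=PhenotypeConfig(kind="homogeneous"),
                seeding=SeedingConfig(mode="sparse", n_cells=50, radius_um=4000.0,
                                      grid_side_sites=600),
                engine=EngineConfig(t_max_h=96.0, record_interval_h=24.0),
                treatment=TreatmentConfig(model="mitotic", p=0.5, schedule="constant"),
                seed=seed,
            )
            res = run_simulation(cfg)
            ratios.append(res.records[-1].n_total / res.records[0].n_total)
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / np.sqrt(len(ratios))
        assert abs(mean - 1.0) < max(3 * se, 0.1)

    def test_extinction_stop_reason(self):
        cfg = RunConfig(
            phenotype=PhenotypeConfig(kind="homogeneous"),
            seeding=SeedingConfig(mode="sparse", n_cells=5, radius_um=500.0,
                                  grid_side_sites=200),
            engine=EngineConfig(t_max_h=600.0, record_interval_h=24.0),
            treatment=TreatmentConfig(model="mitotic", p=1.0, schedule="constant"),
            seed=0,
        )
        res = run_simulation(cfg)
        assert res.stop_reason == "extinct"
        assert res.records[-1].n_total == 0

    def test_invalid_config_reported_before_running(self):
        cfg = self._ten_cell_cfg(96.0)
        bad = RunConfig(
            phenotype=cfg.phenotype,
            seeding=SeedingConfig(mode="sparse", n_cells=10, radius_um=3000.0,
                                  grid_side_sites=200),  # circle + margin > grid
            engine=cfg.engine,
            seed=0,
        )
        with pytest.raises(ValueError):
            run_simulation(bad)
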