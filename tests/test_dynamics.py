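"""Agent rules: cycling, mitosis, migration, multi-hit killing, bookkeeping."""

import numpy as np
import pytest

from gridabm import _kernel
from gridabm.dynamics import (CycleParams, MotionParams, SimulationState,
                              advance_timestep, direction_vector, resolve_hits,
                              step_all_agents, step_cancer, step_immune,
                              submoves_per_timestep)
from gridabm.lattice import Coordinate, nearest_of_class
from gridabm.recruitment import RecruitmentRates


def surround(state, x, y, klass="cancer"):
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx or dy:
                state.add_agent(klass, x + dx, y + dy, div_length=1e9)


class TestSpeedConversion:
    def test_immune_speed_to_submoves(self):
        assert submoves_per_timestep(5.0) == 15

    def test_cancer_speed_to_submoves(self):
        assert submoves_per_timestep(2.3) == 6


class TestDirectionVector:
    def test_pure_directed_motion(self, rng):
        w = direction_vector((0, 0), (3, 4), 1.0, rng)
        assert np.allclose(w, [0.6, 0.8])

    def test_weighted_combination(self):
        w = direction_vector((0, 0), (3, 4), 0.19, v=(1.0, 0.0))
        assert np.allclose(w, [0.924, 0.152])

    def test_zero_eta_is_brownian(self, rng):
        w = direction_vector((0, 0), (3, 4), 0.0, rng)
        assert np.hypot(*w) == pytest.approx(1.0)  # w == v, a unit vector

    def test_degenerate_pair_rejected(self, rng):
        with pytest.raises(ValueError):
            direction_vector((2, 2), (2, 2), 0.19, rng)


class TestCancerStep:
    def test_surrounded_cell_is_quiescent(self, state, cycle):
        c = state.add_agent("cancer", 10, 10, div_length=24.0, cycle_pos=5.0)
        surround(state, 10, 10)
        step_cancer(state, c, MotionParams(p_a=0.0), cycle)
        assert state.cycle_pos[c] == 5.0
        assert state.quiescent[c]

    def test_free_cell_progresses_cycle(self, state, cycle):
        c = state.add_agent("cancer", 10, 10, div_length=24.0, cycle_pos=5.0)
        step_cancer(state, c, MotionParams(p_a=0.0, p_m=0.0), cycle)
        assert state.cycle_pos[c] == 6.0
        assert not state.quiescent[c]

    def test_mitosis_into_single_vacant_neighbor(self, state, cycle):
        c = state.add_agent("cancer", 10, 10, div_length=24.0, cycle_pos=23.5)
        surround(state, 10, 10)
        state.remove_agent(int(state.occ[9, 9]) - 1)  # open exactly (9, 9)
        state.reset_step_counters()
        step_cancer(state, c, MotionParams(p_a=0.0, p_m=0.0), cycle)
        assert state.read_step_deaths().c_mitosis == 1
        assert state.cycle_pos[c] == 0.0
        daughter = int(state.occ[9, 9]) - 1
        assert daughter >= 0 and state.kind[daughter] == _kernel.CANCER
        assert cycle.lo <= state.div_length[daughter] <= cycle.hi

    def test_certain_apoptosis_frees_node_immediately(self, state, cycle):
        c = state.add_agent("cancer", 5, 5, div_length=24.0)
        state.reset_step_counters()
        step_cancer(state, c, MotionParams(p_a=1.0), cycle)
        assert state.read_step_deaths().c_apoptosis == 1
        assert state.occ[5, 5] == 0
        assert state.counts() == (0, 0, 0)

    def test_doomed_cell_removed_at_death_time(self, state, cycle):
        c = state.add_agent("cancer", 5, 5, div_length=24.0)
        state.doomed[c] = True
        state.death_hour[c] = 8.0
        state.hour = 7
        state.reset_step_counters()
        step_cancer(state, c, MotionParams(p_a=0.0), cycle)
        assert state.counts() == (1, 0, 0)  # not yet
        state.hour = 8
        step_cancer(state, c, MotionParams(p_a=0.0), cycle)
        assert state.read_step_deaths().c_tx == 1
        assert state.counts() == (0, 0, 0)

    def test_migration_bounded_by_submove_budget(self, state, cycle):
        c = state.add_agent("cancer", 30, 25, div_length=1e9)
        for _ in range(50):
            x0, y0 = int(state.xs[c]), int(state.ys[c])
            step_cancer(state, c, MotionParams(p_a=0.0, p_m=1.0), cycle)
            moved = max(abs(int(state.xs[c]) - x0), abs(int(state.ys[c]) - y0))
            assert moved <= 6


class TestImmuneStep:
    def test_single_hit_per_timestep(self, state, motion):
        state.add_agent("cancer", 10, 10, div_length=1e9)
        e = state.add_agent("effector", 9, 10)
        step_immune(state, e, MotionParams(immune_submoves=0))
        tgt = int(state.occ[10, 10]) - 1
        assert state.hits_received[tgt] == 1
        assert state.hits_delivered[e] == 1

    def test_three_same_step_hits_kill(self, state, motion):
        state.add_agent("cancer", 10, 10, div_length=1e9)
        es = [state.add_agent("effector", 9, 10),
              state.add_agent("effector", 11, 10),
              state.add_agent("effector", 10, 9)]
        state.reset_step_counters()
        for e in es:
            step_immune(state, e, MotionParams(immune_submoves=0))
        deaths = resolve_hits(state)
        assert deaths.c_effector == 1
        assert state.counts() == (0, 3, 0)
        assert state.read_kill_locations().tolist() == [[10, 10]]

    def test_two_hits_repair_within_timestep(self, state):
        c = state.add_agent("cancer", 10, 10, div_length=1e9)
        for pos in [(9, 10), (11, 10)]:
            e = state.add_agent("effector", *pos)
            step_immune(state, e, MotionParams(immune_submoves=0))
        resolve_hits(state)
        assert state.kind[c] == _kernel.CANCER
        assert state.hits_received[c] == 0  # fully repaired

    def test_damage_does_not_accumulate_across_timesteps(self, state):
        c = state.add_agent("cancer", 10, 10, div_length=1e9)
        for _ in range(2):  # 2 hits at t, 2 hits at t+1
            for pos in [(9, 10), (11, 10)]:
                e = int(state.occ[pos[1], pos[0]]) - 1
                if e < 0:
                    e = state.add_agent("effector", *pos)
                step_immune(state, e, MotionParams(immune_submoves=0))
            resolve_hits(state)
        assert state.kind[c] == _kernel.CANCER

    def test_regulatory_cells_kill_effectors(self, state):
        e = state.add_agent("effector", 10, 10)
        state.hits_delivered[e] = 4
        for pos in [(9, 10), (11, 10), (10, 9)]:
            r = state.add_agent("regulatory", *pos)
            step_immune(state, r, MotionParams(immune_submoves=0))
        resolve_hits(state)
        assert state.counts() == (0, 0, 3)

    def test_tenth_hit_exhausts_and_removes(self, state):
        state.add_agent("cancer", 10, 10, div_length=1e9)
        e = state.add_agent("effector", 9, 10)
        state.hits_delivered[e] = 9
        step_immune(state, e, MotionParams(immune_submoves=0))
        assert state.kind[e] == _kernel.EMPTY
        assert state.counts() == (1, 0, 0)

    def test_lifetime_hits_never_exceed_ten(self, state, motion):
        state.add_agent("cancer", 10, 10, div_length=1e9)
        surround(state, 10, 10)
        e = state.add_agent("effector", 12, 12)
        for _ in range(300):
            if state.kind[e] == _kernel.EMPTY:
                break
            step_immune(state, e, motion)
            assert state.hits_delivered[e] <= 10
        assert state.kind[e] == _kernel.EMPTY  # exhausted eventually

    def test_displacement_bounded_by_submove_budget(self, state, motion):
        e = state.add_agent("effector", 30, 25)
        state.add_agent("cancer", 2, 2, div_length=1e9)
        for _ in range(10):
            x0, y0 = int(state.xs[e]), int(state.ys[e])
            step_immune(state, e, motion)
            moved = max(abs(int(state.xs[e]) - x0), abs(int(state.ys[e]) - y0))
            assert moved <= 15

    def test_directed_motion_approaches_target(self, state, motion):
        # eta_directed = 0.19 gives a weak but persistent drift toward the
        # target (~0.12 nodes per sub-move); over 600 sub-moves the effector
        # closes most of the 68-node start distance
        e = state.add_agent("effector", 5, 5)
        state.add_agent("cancer", 60, 45, div_length=1e9)
        d0 = np.hypot(60 - 5, 45 - 5)
        for _ in range(40):
            step_immune(state, e, motion)
        d1 = np.hypot(60 - int(state.xs[e]), 45 - int(state.ys[e]))
        assert d1 < d0 / 2


class TestKernelNearestTargetParity:
    def test_kernel_choice_always_among_oracle_ties(self, rng):
        """The kernel's nearest-target pick must agree with the pure-Python
        tie set, through both the sparse (list) and dense (ring) paths."""
        for trial in range(60):
            state = SimulationState()
            state.seed_kernel(trial)
            n_targets = int(rng.integers(1, 400))
            placed = set()
            while len(placed) < n_targets:
                placed.add((int(rng.integers(68)), int(rng.integers(51))))
            for x, y in placed:
                state.add_agent("cancer", x, y, div_length=1e9)
            px, py = 33, 25
            if (px, py) in placed:
                continue
            r = float(rng.uniform(2, 50))
            oracle = nearest_of_class(Coordinate(px, py), r,
                                      [Coordinate(x, y) for x, y in placed])
            found, qx, qy = _kernel._nearest_target(
                state.occ, state.kind, state.xs, state.ys, px, py,
                _kernel.CANCER, r, state.c_list, state.meta[7])
            if not oracle:
                assert not found
            else:
                assert found and Coordinate(qx, qy) in oracle


class TestConservation:
    def test_ledger_and_occupancy_conservation_500_steps(self):
        """initial C + births - deaths == final C, and occupied nodes == C+E+R,
        throughout a 500 h mixed run with recruitment active."""
        from gridabm.experiment import SimulationConfig, build_state
        from gridabm.mihc import build_initial_state, generate_synthetic_slide

        cfg = SimulationConfig()
        rng = np.random.default_rng(5)
        init = build_initial_state(generate_synthetic_slide(400, 40, 20, 0.5, 11))
        state = build_state(init, cfg, rng)
        state.seed_kernel(17)
        c0 = state.counts()[0]
        rates = RecruitmentRates(zeta_apoptosis=0.3, zeta_effector=0.3,
                                 mu=0.5, zeta_regulatory=0.3)
        for _ in range(500):
            advance_timestep(state, cfg.motion, cfg.cycle, rates, rng=rng)
            c, e, r = state.counts()
            assert np.count_nonzero(state.occ) == c + e + r
            assert int(state.meta[7]) == c       # class lists stay consistent
            assert int(state.meta[8]) == e
            cum = state.ledger.cumulative()
            deaths = cum.c_apoptosis + cum.c_effector + cum.c_tx
            assert c0 + cum.c_mitosis - deaths == c

    def test_saturation_without_death_channels(self):
        """With immune absent, p_a = 0 and no radiation, C is non-decreasing
        and capped by the node count."""
        state = SimulationState(width=10, height=10)
        state.seed_kernel(3)
        motion = MotionParams(p_a=0.0)
        cycle = CycleParams()
        state.add_agent("cancer", 5, 5, div_length=20.0, cycle_pos=10.0)
        prev = 1
        for _ in range(400):
            state.reset_step_counters()
            step_all_agents(state, motion, cycle)
            state.hour += 1
            c = state.counts()[0]
            assert prev <= c <= 100
            prev = c
        assert prev == 100  # lattice saturated
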