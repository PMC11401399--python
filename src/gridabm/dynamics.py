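"""Per-timestep agent behavior: cancer cycling, mitosis, apoptosis and random
walks; immune directed migration; multi-hit killing; and the orchestrated
hourly update.

Model summary
-------------
Three agent classes share a single-occupancy lattice: cancer cells (C),
anti-tumor effector cells (E, a CD8+ T-cell proxy) and pro-tumor regulatory
cells (R, a Treg proxy).  Each hour:

* Cancer cells die spontaneously with probability ``p_a`` (node freed
  immediately), progress their cell cycle only when a Moore neighbor is
  vacant (otherwise quiescent), divide into a random vacant Moore node on
  cycle completion, and with probability ``p_m`` take up to 6 single-node
  random-walk moves.  Cells doomed by radiation are removed once the 8 h
  death delay elapses.
* Immune cells take up to 15 sub-moves, each biased toward the nearest
  target of their class (effectors seek cancer cells, regulatory cells seek
  effectors) by the direction vector ``w = (1 - eta) v + eta u`` with random
  unit vector ``v`` and target bearing ``u``; with no target in the search
  radius they walk randomly.  After moving they deliver at most one "hit" to
  one adjacent target; three hits within a single timestep kill the target,
  fewer repair fully, and an immune cell is exhausted and removed after its
  10th lifetime hit.

The hot loop is implemented once, in numba kernels (:mod:`gridabm._kernel`);
the functions here are the public surface over the same kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import _kernel
from .lattice import Coordinate

__all__ = [
    "CancerAgent",
    "ImmuneAgent",
    "MotionParams",
    "CycleParams",
    "DeathLedger",
    "StepDeaths",
    "SimulationState",
    "direction_vector",
    "step_cancer",
    "step_immune",
    "resolve_hits",
    "step_all_agents",
    "advance_timestep",
    "submoves_per_timestep",
    "apoptosis_lifetimes",
]

KIND_NAMES = {_kernel.CANCER: "cancer", _kernel.EFFECTOR: "effector",
              _kernel.REGULATORY: "regulatory"}
KIND_CODES = {v: k for k, v in KIND_NAMES.items()}


def submoves_per_timestep(speed_um_per_min: float, node_pitch_um: float = 20.0,
                          dt_hours: float = 1.0) -> int:
    """Convert a migration speed to whole lattice moves per timestep.

    ``floor(speed * 60 * dt / pitch)``: 5 um/min -> 15 nodes/h for immune
    cells, 2.3 um/min -> 6 nodes/h for cancer cells at 20 um pitch.
    """
    return int(math.floor(speed_um_per_min * 60.0 * dt_hours / node_pitch_um))


@dataclass
class MotionParams:
    """Migration and cancer-fate probabilities, per 1 h timestep."""

    eta_directed: float = 0.19          # weight of directed motion
    search_radius: float = 50.0         # target search radius, nodes
    immune_submoves: int = 15           # 5 um/min at 20 um pitch
    cancer_submoves: int = 6            # 2.3 um/min at 20 um pitch
    p_m: float = 0.9                    # cancer migration probability
    p_a: float = 3.0e-3                 # cancer apoptosis probability

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta_directed <= 1.0:
            raise ValueError("eta_directed must lie in [0, 1]")
        for name in ("p_m", "p_a"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.search_radius <= 0:
            raise ValueError("search_radius must be positive")

    @property
    def eta_rnd(self) -> float:
        return 1.0 - self.eta_directed


@dataclass
class CycleParams:
    """Cell-cycle length distribution: truncated normal, hours."""

    mean: float = 24.0
    sd: float = 2.0
    lo: float = 18.0
    hi: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.lo <= self.mean <= self.hi):
            raise ValueError("require 0 < lo <= mean <= hi")


@dataclass
class CancerAgent:
    """Snapshot of a cancer agent (read-only view of kernel state)."""

    position: Coordinate
    div_length: float
    cycle_position: float
    doomed: bool = False
    death_time: Optional[float] = None


@dataclass
class ImmuneAgent:
    """Snapshot of an immune agent."""

    position: Coordinate
    klass: str  # "effector" | "regulatory"
    hits_delivered: int = 0


@dataclass
class StepDeaths:
    """Closed single-timestep ledger row."""

    c_apoptosis: int = 0
    c_effector: int = 0
    c_tx: int = 0
    c_mitosis: int = 0


class DeathLedger:
    """Per-timestep cancer-death and mitosis counts, by mechanism.

    Drives immune recruitment (deaths at t recruit at t+1) and end-of-run
    mechanism attribution.
    """

    def __init__(self) -> None:
        self.hours: List[int] = []
        self.apoptosis: List[int] = []
        self.effector: List[int] = []
        self.radiation: List[int] = []
        self.mitosis: List[int] = []

    def append(self, hour: int, row: StepDeaths) -> None:
        self.hours.append(hour)
        self.apoptosis.append(row.c_apoptosis)
        self.effector.append(row.c_effector)
        self.radiation.append(row.c_tx)
        self.mitosis.append(row.c_mitosis)

    @property
    def last(self) -> StepDeaths:
        if not self.hours:
            return StepDeaths()
        return StepDeaths(self.apoptosis[-1], self.effector[-1],
                          self.radiation[-1], self.mitosis[-1])

    def cumulative(self) -> StepDeaths:
        return StepDeaths(int(sum(self.apoptosis)), int(sum(self.effector)),
                          int(sum(self.radiation)), int(sum(self.mitosis)))


class SimulationState:
    """Array-backed population state on a single-occupancy lattice.

    ``capacity`` defaults to twice the node count so that slots freed during
    a step need never be reused within that step (births are bounded by the
    vacancy count).
    """

    def __init__(self, width: int = 68, height: int = 51,
                 node_pitch: float = 20.0, capacity: Optional[int] = None):
        self.width = int(width)
        self.height = int(height)
        self.node_pitch = float(node_pitch)
        cap = int(capacity) if capacity is not None else 2 * self.width * self.height
        self.capacity = cap
        self.kind = np.zeros(cap, np.int8)
        self.xs = np.zeros(cap, np.int64)
        self.ys = np.zeros(cap, np.int64)
        self.div_length = np.full(cap, np.inf)
        self.cycle_pos = np.zeros(cap)
        self.doomed = np.zeros(cap, np.bool_)
        self.death_hour = np.full(cap, _kernel.NO_DEATH)
        self.quiescent = np.zeros(cap, np.bool_)
        self.hits_delivered = np.zeros(cap, np.int64)
        self.hits_received = np.zeros(cap, np.int64)
        self.occ = np.zeros((self.height, self.width), np.int64)
        self.free_stack = np.arange(cap - 1, -1, -1, dtype=np.int64)
        self.dead_buf = np.zeros(cap, np.int64)
        self.meta = np.zeros(10, np.int64)
        self.meta[0] = cap
        # live-slot lists for the two targetable classes (O(1) swap-remove)
        self.c_list = np.zeros(cap, np.int64)
        self.e_list = np.zeros(cap, np.int64)
        self.slot_pos = np.zeros(cap, np.int64)
        self.kill_x = np.zeros(cap, np.int64)
        self.kill_y = np.zeros(cap, np.int64)
        self.hour = 0
        self.ledger = DeathLedger()
        self.prev_kills: np.ndarray = np.empty((0, 2), np.int64)
        self.n_discarded_recruits = 0

    # -- occupancy bookkeeping -------------------------------------------

    def seed_kernel(self, seed_value: int) -> None:
        _kernel.seed(int(seed_value) & 0xFFFFFFFF)

    def contains(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def is_vacant(self, x: int, y: int) -> bool:
        return self.occ[y, x] == 0

    def add_agent(self, klass: Union[str, int], x: int, y: int, *,
                  div_length: float = np.inf, cycle_pos: float = 0.0) -> int:
        code = KIND_CODES[klass] if isinstance(klass, str) else int(klass)
        if not self.contains(x, y):
            raise ValueError(f"({x}, {y}) outside domain")
        if self.occ[y, x] != 0:
            raise ValueError(f"node ({x}, {y}) already occupied")
        self.meta[0] -= 1
        idx = int(self.free_stack[self.meta[0]])
        self.kind[idx] = code
        self.xs[idx] = x
        self.ys[idx] = y
        self.div_length[idx] = div_length
        self.cycle_pos[idx] = cycle_pos
        self.doomed[idx] = False
        self.death_hour[idx] = _kernel.NO_DEATH
        self.quiescent[idx] = False
        self.hits_delivered[idx] = 0
        self.hits_received[idx] = 0
        self.occ[y, x] = idx + 1
        if code == _kernel.CANCER:
            _kernel._list_add(idx, self.c_list, self.slot_pos, self.meta, 7)
        elif code == _kernel.EFFECTOR:
            _kernel._list_add(idx, self.e_list, self.slot_pos, self.meta, 8)
        return idx

    def remove_agent(self, idx: int) -> None:
        if self.kind[idx] == _kernel.EMPTY:
            raise ValueError(f"slot {idx} is empty")
        code = int(self.kind[idx])
        if code == _kernel.CANCER:
            _kernel._list_remove(idx, self.c_list, self.slot_pos, self.meta, 7)
        elif code == _kernel.EFFECTOR:
            _kernel._list_remove(idx, self.e_list, self.slot_pos, self.meta, 8)
        self.occ[self.ys[idx], self.xs[idx]] = 0
        self.kind[idx] = _kernel.EMPTY
        self.free_stack[self.meta[0]] = idx
        self.meta[0] += 1

    def live_indices(self, klass: Optional[Union[str, int]] = None) -> np.ndarray:
        if klass is None:
            return np.flatnonzero(self.kind != _kernel.EMPTY)
        code = KIND_CODES[klass] if isinstance(klass, str) else int(klass)
        return np.flatnonzero(self.kind == code)

    def counts(self) -> Tuple[int, int, int]:
        """(C, E, R) live-agent counts."""
        return (int(np.count_nonzero(self.kind == _kernel.CANCER)),
                int(np.count_nonzero(self.kind == _kernel.EFFECTOR)),
                int(np.count_nonzero(self.kind == _kernel.REGULATORY)))

    def n_live(self) -> int:
        return int(np.count_nonzero(self.kind != _kernel.EMPTY))

    def vacant_nodes(self) -> np.ndarray:
        """(n, 2) array of vacant (x, y) node indices in raster order."""
        ys, xs = np.nonzero(self.occ == 0)
        return np.column_stack([xs, ys])

    def get_agent(self, idx: int) -> Union[CancerAgent, ImmuneAgent]:
        code = int(self.kind[idx])
        pos = Coordinate(int(self.xs[idx]), int(self.ys[idx]))
        if code == _kernel.CANCER:
            dt = float(self.death_hour[idx])
            return CancerAgent(pos, float(self.div_length[idx]),
                               float(self.cycle_pos[idx]), bool(self.doomed[idx]),
                               dt if dt < _kernel.NO_DEATH else None)
        if code in (_kernel.EFFECTOR, _kernel.REGULATORY):
            return ImmuneAgent(pos, KIND_NAMES[code], int(self.hits_delivered[idx]))
        raise ValueError(f"slot {idx} is empty")

    def agents(self) -> Iterator[Union[CancerAgent, ImmuneAgent]]:
        for idx in self.live_indices():
            yield self.get_agent(int(idx))

    # -- kernel plumbing --------------------------------------------------

    def _arrays(self) -> tuple:
        return (self.kind, self.xs, self.ys, self.div_length, self.cycle_pos,
                self.doomed, self.death_hour, self.quiescent,
                self.hits_delivered, self.hits_received, self.occ,
                self.free_stack, self.dead_buf, self.meta,
                self.c_list, self.e_list, self.slot_pos)

    def reset_step_counters(self) -> None:
        self.meta[2:7] = 0

    def read_step_deaths(self) -> StepDeaths:
        return StepDeaths(int(self.meta[2]), int(self.meta[3]),
                          int(self.meta[4]), int(self.meta[5]))

    def read_kill_locations(self) -> np.ndarray:
        n = int(self.meta[6])
        return np.column_stack([self.kill_x[:n], self.kill_y[:n]]).copy()


def direction_vector(p: Sequence[float], q: Sequence[float], eta_directed: float,
                     rng: Optional[np.random.Generator] = None,
                     v: Optional[Sequence[float]] = None) -> np.ndarray:
    """Immune migration direction ``w = (1 - eta) v + eta u``.

    ``u`` is the unit bearing from ``p`` to ``q``; ``v`` a uniformly random
    unit vector (drawn from ``rng`` unless supplied explicitly, e.g. in
    tests).  ``w`` is not re-normalized -- only its direction is consumed.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d = q - p
    nrm = float(np.hypot(d[0], d[1]))
    if nrm == 0.0:
        raise ValueError("degenerate direction: p == q")
    u = d / nrm
    if v is None:
        if rng is None:
            raise ValueError("either rng or v must be provided")
        ang = rng.uniform(0.0, 2.0 * np.pi)
        v = np.array([np.cos(ang), np.sin(ang)])
    else:
        v = np.asarray(v, float)
    return (1.0 - eta_directed) * v + eta_directed * u


def step_cancer(state: SimulationState, idx: int, params: MotionParams,
                cycle: CycleParams) -> None:
    """Advance one cancer agent through its hourly rule set (see module doc)."""
    if state.kind[idx] != _kernel.CANCER:
        raise ValueError(f"slot {idx} does not hold a cancer agent")
    _kernel.step_cancer(int(idx), *state._arrays(), float(state.hour),
                        params.p_a, params.p_m, params.cancer_submoves,
                        cycle.mean, cycle.sd, cycle.lo, cycle.hi)
    _kernel.merge_freed(state.free_stack, state.dead_buf, state.meta)


def step_immune(state: SimulationState, idx: int, params: MotionParams) -> None:
    """Advance one immune agent: 15 target-seeking sub-moves then <=1 hit."""
    if state.kind[idx] not in (_kernel.EFFECTOR, _kernel.REGULATORY):
        raise ValueError(f"slot {idx} does not hold an immune agent")
    _kernel.step_immune(int(idx), *state._arrays(), float(state.hour),
                        params.eta_directed, params.search_radius,
                        params.immune_submoves)
    _kernel.merge_freed(state.free_stack, state.dead_buf, state.meta)


def resolve_hits(state: SimulationState) -> StepDeaths:
    """Kill every target with >=3 same-step hits; reset all hit counters."""
    _kernel.resolve_hits(state.kind, state.xs, state.ys, state.hits_received,
                         state.occ, state.dead_buf, state.meta,
                         state.kill_x, state.kill_y,
                         state.c_list, state.e_list, state.slot_pos)
    _kernel.merge_freed(state.free_stack, state.dead_buf, state.meta)
    return state.read_step_deaths()


def step_all_agents(state: SimulationState, params: MotionParams,
                    cycle: CycleParams) -> StepDeaths:
    """Shuffled pass over all live agents plus hit resolution (phases 3-4)."""
    _kernel.step_all(*state._arrays(), state.kill_x, state.kill_y,
                     float(state.hour), params.p_a, params.p_m,
                     params.cancer_submoves, cycle.mean, cycle.sd, cycle.lo,
                     cycle.hi, params.eta_directed, params.search_radius,
                     params.immune_submoves)
    return state.read_step_deaths()


def advance_timestep(state: SimulationState, motion: MotionParams,
                     cycle: CycleParams, rates, radio=None, schedule=None,
                     rng: Optional[np.random.Generator] = None) -> StepDeaths:
    """One full hour, in fixed phase order.

    1. place immune recruits computed from the *previous* step's ledger;
    2. apply a radiation fraction if one is scheduled at this hour;
    3. shuffle and step every agent; 4. resolve hits; 5. close the ledger.

    Returns the closed ledger row for this step; population counts should be
    read after return.
    """
    from . import radiation as _radiation
    from . import recruitment as _recruitment

    hour = state.hour
    if rates is not None:
        counts = _recruitment.compute_recruits(state.ledger.last, rates)
        _recruitment.place_recruits(counts, state.prev_kills, rates.mu, state, rng)
    if schedule is not None and radio is not None:
        dose_map = schedule.fraction_at(hour)
        if dose_map is not None:
            _radiation.apply_fraction(state, dose_map, radio, rng)
    state.reset_step_counters()
    step_all_agents(state, motion, cycle)
    row = state.read_step_deaths()
    state.prev_kills = state.read_kill_locations()
    state.ledger.append(hour, row)
    state.hour = hour + 1
    return row


def apoptosis_lifetimes(n_agents: int, p_a: float = 3.0e-3,
                        seed: int = 0) -> np.ndarray:
    """Empirical lifetimes (hours) of cancer agents with apoptosis as the only
    death channel.

    Agents are stepped through the full cancer rule set with migration off and
    an unreachable division length, in whole-lattice batches, until each has
    died; the resulting lifetimes are geometric with mean ``1/p_a`` (about
    14 days at the default rate).
    """
    motion = MotionParams(p_a=p_a, p_m=0.0)
    cycle = CycleParams()
    out = np.empty(n_agents)
    done = 0
    batch_id = 0
    while done < n_agents:
        state = SimulationState()
        state.seed_kernel(seed + batch_id)
        batch = min(n_agents - done, state.width * state.height)
        slots = []
        placed = 0
        for y in range(state.height):
            for x in range(state.width):
                if placed >= batch:
                    break
                slots.append(state.add_agent("cancer", x, y, div_length=1e12))
                placed += 1
        alive = set(slots)
        while alive:
            state.reset_step_counters()
            step_all_agents(state, motion, cycle)
            state.hour += 1
            for idx in [i for i in alive if state.kind[i] == _kernel.EMPTY]:
                out[done] = state.hour
                done += 1
                alive.discard(idx)
        batch_id += 1
    return out
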