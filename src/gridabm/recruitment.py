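"""Immune recruitment: convert the previous hour's death/mitosis ledger into
newly placed immune agents.

Four channels feed recruitment, each with its own rate (recruited cells per
triggering event in the preceding timestep):

* cancer apoptosis -> effectors (``zeta_apoptosis``), placed uniformly at
  random on vacant nodes (uniform blood-vessel assumption);
* effector-mediated cancer kills -> effectors (``zeta_effector``); each such
  recruit homes, with probability ``mu``, to a vacant node within 10 nodes of
  a uniformly chosen kill site from the previous step ("post-code" placement),
  otherwise it is placed globally at random;
* radiation-induced cancer deaths -> effectors (``zeta_tx``, the
  immunogenicity of radiation kill: 0 none, 0.01 low, 0.1 high), placed
  globally at random;
* mitoses -> regulatory cells (``zeta_regulatory``), placed globally at
  random.

Rates are typically below one recruit per event; fractional parts carry over
between timesteps (floor-with-carry), so long-run recruitment equals
rate x events to within one cell per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .dynamics import SimulationState, StepDeaths
from .lattice import Coordinate, disk_offsets

__all__ = ["RecruitmentRates", "RecruitCounts", "compute_recruits", "place_recruits"]

POSTCODE_RADIUS = 10.0  # nodes


@dataclass
class RecruitmentRates:
    """Recruitment rates plus their fractional-remainder accumulators."""

    zeta_apoptosis: float = 0.2
    zeta_effector: float = 0.4
    mu: float = 0.5
    zeta_regulatory: float = 0.2
    zeta_tx: float = 0.0
    acc_apoptosis: float = 0.0
    acc_effector: float = 0.0
    acc_tx: float = 0.0
    acc_regulatory: float = 0.0

    def __post_init__(self) -> None:
        for name in ("zeta_apoptosis", "zeta_effector", "zeta_regulatory", "zeta_tx"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")


@dataclass
class RecruitCounts:
    """Integer recruit counts for the next timestep, by channel."""

    e_apoptosis: int = 0
    e_effector: int = 0
    e_tx: int = 0
    r_regulatory: int = 0

    @property
    def total(self) -> int:
        return self.e_apoptosis + self.e_effector + self.e_tx + self.r_regulatory


def _floor_carry(rate: float, count: int, acc: float) -> Tuple[int, float]:
    raw = rate * count + acc
    n = int(np.floor(raw))
    return n, raw - n


def compute_recruits(ledger_row: StepDeaths, rates: RecruitmentRates) -> RecruitCounts:
    """Recruits for t+1 from the closed ledger of timestep t.

    Per channel: ``raw = rate * count + accumulator``; the integer part is
    recruited and the fractional part carried to the next call (the
    accumulators on ``rates`` are updated in place).
    """
    e_apop, rates.acc_apoptosis = _floor_carry(
        rates.zeta_apoptosis, ledger_row.c_apoptosis, rates.acc_apoptosis)
    e_eff, rates.acc_effector = _floor_carry(
        rates.zeta_effector, ledger_row.c_effector, rates.acc_effector)
    e_tx, rates.acc_tx = _floor_carry(
        rates.zeta_tx, ledger_row.c_tx, rates.acc_tx)
    r_reg, rates.acc_regulatory = _floor_carry(
        rates.zeta_regulatory, ledger_row.c_mitosis, rates.acc_regulatory)
    return RecruitCounts(e_apop, e_eff, e_tx, r_reg)


def _place_global(state: SimulationState, klass: str,
                  rng: np.random.Generator) -> Optional[Coordinate]:
    vac = state.vacant_nodes()
    if vac.shape[0] == 0:
        return None
    x, y = vac[rng.integers(vac.shape[0])]
    state.add_agent(klass, int(x), int(y))
    return Coordinate(int(x), int(y))


def _place_postcode(state: SimulationState, kill_locations: np.ndarray,
                    rng: np.random.Generator) -> Optional[Coordinate]:
    """Vacant node within POSTCODE_RADIUS of a uniformly chosen kill site;
    falls back to global placement when the whole disk is occupied."""
    loc = kill_locations[rng.integers(kill_locations.shape[0])]
    offs = disk_offsets(POSTCODE_RADIUS, include_center=True)
    cand = offs + np.asarray(loc, np.int64)
    ok = ((cand[:, 0] >= 0) & (cand[:, 0] < state.width)
          & (cand[:, 1] >= 0) & (cand[:, 1] < state.height))
    cand = cand[ok]
    vacant = cand[state.occ[cand[:, 1], cand[:, 0]] == 0]
    if vacant.shape[0] == 0:
        return _place_global(state, "effector", rng)
    x, y = vacant[rng.integers(vacant.shape[0])]
    state.add_agent("effector", int(x), int(y))
    return Coordinate(int(x), int(y))


def place_recruits(counts: RecruitCounts, kill_locations: np.ndarray,
                   mu: float, state: SimulationState,
                   rng: np.random.Generator) -> List[Tuple[Coordinate, str]]:
    """Place the computed recruits on the lattice; returns placements made.

    Recruits that find no vacant node anywhere are discarded and counted on
    ``state.n_discarded_recruits``.
    """
    kill_locations = np.asarray(kill_locations, np.int64).reshape(-1, 2)
    placements: List[Tuple[Coordinate, str]] = []

    def book(coord: Optional[Coordinate], klass: str) -> None:
        if coord is None:
            state.n_discarded_recruits += 1
        else:
            placements.append((coord, klass))

    for _ in range(counts.e_apoptosis):
        book(_place_global(state, "effector", rng), "effector")
    for _ in range(counts.e_tx):
        book(_place_global(state, "effector", rng), "effector")
    for _ in range(counts.e_effector):
        if kill_locations.shape[0] > 0 and rng.random() < mu:
            book(_place_postcode(state, kill_locations, rng), "effector")
        else:
            book(_place_global(state, "effector", rng), "effector")
    for _ in range(counts.r_regulatory):
        book(_place_global(state, "regulatory", rng), "regulatory")
    return placements
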