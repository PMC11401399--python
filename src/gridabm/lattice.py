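"""Discrete spatial substrate for the tumor-immune lattice model.

The simulated tissue section is a fixed rectangular grid of square nodes
(default 68 x 51 nodes at 20 um pitch, i.e. ~1.39 mm^2), each of which can
hold at most one cell agent.  The node pitch equals the assumed average cell
diameter, so occupancy is exclusive by construction.  All spatial queries --
Moore neighborhoods, disk (radius) queries, nearest-target searches -- operate
on integer node indices with the Euclidean metric, and the domain is closed:
there is no wraparound and agents cannot leave the grid.

Coordinates are 0-based ``(x, y)`` node indices with ``x`` along the width.
Neighbor and disk queries return nodes in deterministic raster order (row by
row, left to right) so that any random tie-breaking downstream is driven
solely by the caller's seeded RNG.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Iterable, List, NamedTuple

import numpy as np

__all__ = [
    "Coordinate",
    "CoordinateError",
    "LatticeDomain",
    "moore_neighbors",
    "nodes_within_radius",
    "disk_offsets",
    "nearest_of_class",
]


class Coordinate(NamedTuple):
    """A 0-based integer lattice node index."""

    x: int
    y: int


class CoordinateError(ValueError):
    """A coordinate falls outside the lattice domain."""


@dataclass
class LatticeDomain:
    """A rectangular single-occupancy lattice.

    Parameters
    ----------
    width, height
        Number of nodes along x and y (defaults 68 x 51).
    node_pitch
        Physical edge length of one node in micrometres (default 20 um,
        the assumed mean cell diameter).
    occupancy
        Mapping from occupied node to an opaque agent identifier.  Every
        node holds zero or one agents at all times.
    """

    width: int = 68
    height: int = 51
    node_pitch: float = 20.0
    occupancy: Dict[Coordinate, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("domain dimensions must be positive")
        if self.node_pitch <= 0:
            raise ValueError("node_pitch must be positive")

    @property
    def n_nodes(self) -> int:
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        """Physical domain area in mm^2 (1.3872 mm^2 for the default grid)."""
        return self.width * self.height * (self.node_pitch / 1000.0) ** 2

    def contains(self, c: Coordinate) -> bool:
        return 0 <= c[0] < self.width and 0 <= c[1] < self.height

    def _require_inside(self, c: Coordinate) -> Coordinate:
        c = Coordinate(int(c[0]), int(c[1]))
        if not self.contains(c):
            raise CoordinateError(f"coordinate {tuple(c)} outside {self.width}x{self.height} domain")
        return c

    def is_vacant(self, c: Coordinate) -> bool:
        return self._require_inside(c) not in self.occupancy

    def place(self, c: Coordinate, agent_id: int) -> None:
        c = self._require_inside(c)
        if c in self.occupancy:
            raise ValueError(f"node {tuple(c)} already occupied by agent {self.occupancy[c]}")
        self.occupancy[c] = agent_id

    def remove(self, c: Coordinate) -> int:
        c = self._require_inside(c)
        try:
            return self.occupancy.pop(c)
        except KeyError:
            raise ValueError(f"node {tuple(c)} is vacant") from None

    def move(self, src: Coordinate, dst: Coordinate) -> None:
        agent = self.remove(src)
        try:
            self.place(dst, agent)
        except ValueError:
            self.occupancy[self._require_inside(src)] = agent
            raise

    def vacant_nodes(self) -> List[Coordinate]:
        occ = self.occupancy
        return [
            Coordinate(x, y)
            for y in range(self.height)
            for x in range(self.width)
            if (x, y) not in occ
        ]


def moore_neighbors(c: Coordinate, dom: LatticeDomain) -> List[Coordinate]:
    """In-bounds nodes at Chebyshev distance 1 from ``c`` (at most 8).

    Raises :class:`CoordinateError` if ``c`` lies outside the domain.  The
    center node is never included; order is raster order.
    """
    cx, cy = dom._require_inside(c)
    out = []
    for dy in (-1, 0, 1):
        ny = cy + dy
        if not 0 <= ny < dom.height:
            continue
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nx = cx + dx
            if 0 <= nx < dom.width:
                out.append(Coordinate(nx, ny))
    return out


@lru_cache(maxsize=64)
def disk_offsets(r: float, include_center: bool = False) -> np.ndarray:
    """Integer offsets ``(dx, dy)`` with Euclidean norm in ``(0, r]``.

    Cached, returned as an ``(n, 2)`` int array in raster order.  With
    ``include_center`` the zero offset is included (norm 0 <= r).
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    k = int(math.floor(r))
    r2 = r * r
    rows = []
    for dy in range(-k, k + 1):
        for dx in range(-k, k + 1):
            d2 = dx * dx + dy * dy
            if d2 <= r2 and (include_center or d2 > 0):
                rows.append((dx, dy))
    return np.array(rows, dtype=np.int64).reshape(-1, 2)


def nodes_within_radius(c: Coordinate, r: float, dom: LatticeDomain) -> List[Coordinate]:
    """All in-bounds nodes at Euclidean distance in ``(0, r]`` from ``c``.

    Excludes ``c`` itself.  ``r`` is in node units; ``r <= 0`` is a
    parameter error.
    """
    cx, cy = dom._require_inside(c)
    out = []
    for dx, dy in disk_offsets(float(r)):
        nx, ny = cx + int(dx), cy + int(dy)
        if 0 <= nx < dom.width and 0 <= ny < dom.height:
            out.append(Coordinate(nx, ny))
    return out


def nearest_of_class(
    c: Coordinate, r: float, targets: Iterable[Coordinate]
) -> List[Coordinate]:
    """Targets within radius ``r`` of ``c`` at minimal Euclidean distance.

    Returns *all* tied nearest targets (the caller breaks ties at random);
    an empty list when no target lies within range.  A target collocated
    with ``c`` would be at distance 0 and is returned alone, though in a
    single-occupancy lattice that situation does not arise.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    r2 = float(r) * float(r)
    best: float = math.inf
    ties: List[Coordinate] = []
    for t in targets:
        d2 = (t[0] - c[0]) ** 2 + (t[1] - c[1]) ** 2
        if d2 > r2:
            continue
        if d2 < best:
            best = d2
            ties = [Coordinate(int(t[0]), int(t[1]))]
        elif d2 == best:
            ties.append(Coordinate(int(t[0]), int(t[1])))
    return ties
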