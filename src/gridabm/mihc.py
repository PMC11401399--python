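"""Read HALO-style per-cell tables, map cells onto the lattice, and generate
synthetic slides.

A multiplex-IHC slide, after segmentation and phenotyping, is a table with
one row per cell: a bounding box in micrometres (``XMin``/``XMax``/``YMin``/
``YMax``) and a phenotype label.  Box centers are mapped to lattice nodes by
``floor(center / kappa)`` with the conversion factor ``kappa`` (default 20 um,
the assumed mean cell diameter).  Distinct cells whose centers fall in the
same node collide; the first row in file order wins, so the fraction of
retained cells decreases as ``kappa`` grows.

The synthetic generator emulates such a slide on the default 1360 x 1020 um
field: a Gaussian cancer-cell mass plus immune cells mixed between uniform
scatter and accumulation near the tumor margin, so both immune-desert
(few immune cells, low clustering) and inflamed (many, high clustering)
microenvironments can be produced without patient data.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .lattice import Coordinate, LatticeDomain

__all__ = [
    "CellTableRow",
    "CellTableColumns",
    "CellTableSchemaError",
    "CellTableParseError",
    "PhenotypeMap",
    "InitialState",
    "read_cell_table",
    "map_cell_to_node",
    "build_initial_state",
    "generate_synthetic_slide",
    "write_cell_table",
]

AGENT_CLASSES = ("cancer", "effector", "regulatory", "ignore")


class CellTableSchemaError(ValueError):
    """The table lacks a required column."""


class CellTableParseError(ValueError):
    """A table cell could not be parsed; the message names the row."""


@dataclass(frozen=True)
class CellTableColumns:
    """Configurable column names of a HALO-style export."""

    x_min: str = "XMin"
    x_max: str = "XMax"
    y_min: str = "YMin"
    y_max: str = "YMax"
    phenotype: str = "Phenotype"


@dataclass(frozen=True)
class CellTableRow:
    """One segmented cell: bounding box (um) plus phenotype label."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    phenotype: str

    def center(self) -> Tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


#: Marker-combination -> agent-class reduction.  Pan-cytokeratin marks tumor
#: cells; CD3+CD8+ cytotoxic T cells are effectors; CD3+CD4+FOXP3+ Tregs are
#: regulatory.  Macrophages (CD68+) and non-regulatory helpers are excluded
#: from the three-class model.
DEFAULT_PHENOTYPE_MAPPING: Dict[str, str] = {
    "PCK+": "cancer",
    "CD3+CD8+": "effector",
    "CD3+CD4+FOXP3+": "regulatory",
    "CD3+CD4+FOXP3-": "ignore",
    "CD68+": "ignore",
}


@dataclass
class PhenotypeMap:
    """Total mapping from phenotype label to agent class."""

    mapping: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MAPPING))

    def __post_init__(self) -> None:
        bad = {v for v in self.mapping.values()} - set(AGENT_CLASSES)
        if bad:
            raise ValueError(f"unknown agent classes in mapping: {sorted(bad)}")
        if "cancer" not in self.mapping.values():
            raise ValueError("at least one phenotype must map to cancer")

    def klass(self, phenotype: str) -> str:
        try:
            return self.mapping[phenotype]
        except KeyError:
            raise KeyError(
                f"phenotype {phenotype!r} not covered by the phenotype map"
            ) from None


def read_cell_table(path, columns: CellTableColumns = CellTableColumns(),
                    delimiter: str = ",") -> List[CellTableRow]:
    """Parse a HALO-style CSV into rows, preserving file order.

    Raises :class:`CellTableSchemaError` when a required column is missing and
    :class:`CellTableParseError` (naming the offending data row, 1-based) for
    non-numeric coordinates, inverted boxes, or empty phenotypes.
    """
    df = pd.read_csv(path, delimiter=delimiter)
    required = [columns.x_min, columns.x_max, columns.y_min, columns.y_max,
                columns.phenotype]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CellTableSchemaError(
            f"missing required column(s) {missing} in {path}")
    coords = {}
    for col in required[:4]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise CellTableParseError(
                f"non-numeric value in column {col!r} at data row {bad[0] + 1}")
        coords[col] = vals.to_numpy(float)
    phen = df[columns.phenotype]
    rows: List[CellTableRow] = []
    for i in range(len(df)):
        p = phen.iloc[i]
        if pd.isna(p) or str(p).strip() == "":
            raise CellTableParseError(f"empty phenotype at data row {i + 1}")
        row = CellTableRow(coords[columns.x_min][i], coords[columns.x_max][i],
                           coords[columns.y_min][i], coords[columns.y_max][i],
                           str(p))
        if row.x_min > row.x_max or row.y_min > row.y_max:
            raise CellTableParseError(f"inverted bounding box at data row {i + 1}")
        rows.append(row)
    return rows


def write_cell_table(rows: Sequence[CellTableRow], path,
                     columns: CellTableColumns = CellTableColumns()) -> None:
    df = pd.DataFrame({
        columns.x_min: [r.x_min for r in rows],
        columns.x_max: [r.x_max for r in rows],
        columns.y_min: [r.y_min for r in rows],
        columns.y_max: [r.y_max for r in rows],
        columns.phenotype: [r.phenotype for r in rows],
    })
    df.to_csv(path, index=False)


def map_cell_to_node(row: CellTableRow, kappa: float) -> Coordinate:
    """``floor(center / kappa)`` componentwise: box center -> node index."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    cx, cy = row.center()
    return Coordinate(int(math.floor(cx / kappa)), int(math.floor(cy / kappa)))


@dataclass
class InitialState:
    """Lattice-mapped initial agent population plus retention bookkeeping."""

    entries: List[Tuple[Coordinate, str]]
    retention_fraction: float
    kappa: float
    n_input: int = 0
    n_ignored: int = 0
    n_out_of_domain: int = 0
    n_collided: int = 0

    def counts(self) -> Dict[str, int]:
        out = {"cancer": 0, "effector": 0, "regulatory": 0}
        for _, klass in self.entries:
            out[klass] += 1
        return out

    def save(self, tsv_path) -> None:
        tsv_path = Path(tsv_path)
        with open(tsv_path, "w") as fh:
            fh.write("x\ty\tclass\n")
            for (x, y), klass in self.entries:
                fh.write(f"{x}\t{y}\t{klass}\n")
        sidecar = {
            "kappa": self.kappa,
            "retention_fraction": self.retention_fraction,
            "counts": self.counts(),
            "n_input": self.n_input,
            "n_ignored": self.n_ignored,
            "n_out_of_domain": self.n_out_of_domain,
            "n_collided": self.n_collided,
        }
        tsv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, tsv_path) -> "InitialState":
        tsv_path = Path(tsv_path)
        entries = []
        with open(tsv_path) as fh:
            next(fh)
            for line in fh:
                x, y, klass = line.split()
                entries.append((Coordinate(int(x), int(y)), klass))
        meta = json.loads(tsv_path.with_suffix(".json").read_text())
        return cls(entries, meta["retention_fraction"], meta["kappa"],
                   meta.get("n_input", 0), meta.get("n_ignored", 0),
                   meta.get("n_out_of_domain", 0), meta.get("n_collided", 0))


def build_initial_state(rows: Sequence[CellTableRow],
                        phenotype_map: Optional[PhenotypeMap] = None,
                        kappa: float = 20.0,
                        dom: Optional[LatticeDomain] = None,
                        offset_um: Tuple[float, float] = (0.0, 0.0),
                        ) -> InitialState:
    """Map table rows onto the lattice and resolve node collisions.

    Rows whose phenotype maps to ``ignore`` are skipped and excluded from the
    retention denominator.  Rows mapping outside the domain are dropped and
    counted as lost; when several rows map to the same node the first in file
    order is retained.  ``retention_fraction`` is retained / non-ignored rows.
    """
    if phenotype_map is None:
        phenotype_map = PhenotypeMap()
    if dom is None:
        dom = LatticeDomain()
    entries: List[Tuple[Coordinate, str]] = []
    taken: Dict[Coordinate, None] = {}
    n_ignored = n_oob = n_collided = 0
    for row in rows:
        klass = phenotype_map.klass(row.phenotype)
        if klass == "ignore":
            n_ignored += 1
            continue
        shifted = CellTableRow(row.x_min - offset_um[0], row.x_max - offset_um[0],
                               row.y_min - offset_um[1], row.y_max - offset_um[1],
                               row.phenotype)
        node = map_cell_to_node(shifted, kappa)
        if not dom.contains(node):
            n_oob += 1
            continue
        if node in taken:
            n_collided += 1
            continue
        taken[node] = None
        entries.append((node, klass))
    denom = len(rows) - n_ignored
    retention = len(entries) / denom if denom else 1.0
    state = InitialState(entries, retention, kappa, len(rows), n_ignored,
                         n_oob, n_collided)
    if state.counts()["cancer"] == 0:
        warnings.warn("no cancer cells retained: simulation would start "
                      "tumor-free", stacklevel=2)
    return state


def generate_synthetic_slide(n_cancer: int, n_effector: int, n_regulatory: int,
                             clustering: float, seed: int,
                             field_width_um: float = 1360.0,
                             field_height_um: float = 1020.0,
                             n_clumps: int = 1,
                             clump_sigma_um: float = 250.0,
                             box_size_um: float = 20.0,
                             ) -> List[CellTableRow]:
    """Synthetic HALO-style table emulating a biopsy field.

    Cancer cells are drawn from ``n_clumps`` Gaussian clumps (one clump sits
    at the field center); immune cells are placed near the tumor-margin ring
    with probability ``clustering`` and uniformly otherwise.  Bounding boxes
    are ``box_size_um`` squares clipped to the field.  Deterministic for a
    fixed seed.

    Raises ``ValueError`` when the requested counts exceed the lattice
    capacity at kappa = ``box_size_um``.
    """
    for name, n in (("n_cancer", n_cancer), ("n_effector", n_effector),
                    ("n_regulatory", n_regulatory)):
        if n < 0:
            raise ValueError(f"{name} must be non-negative")
    if not 0.0 <= clustering <= 1.0:
        raise ValueError("clustering must lie in [0, 1]")
    capacity = (int(field_width_um // box_size_um)
                * int(field_height_um // box_size_um))
    total = n_cancer + n_effector + n_regulatory
    if total > capacity:
        raise ValueError(
            f"requested {total} cells exceed the {capacity}-node lattice capacity")
    rng = np.random.default_rng(seed)
    center = np.array([field_width_um / 2.0, field_height_um / 2.0])
    clump_centers = [center]
    for _ in range(1, max(1, n_clumps)):
        clump_centers.append(np.array([
            rng.uniform(0.25 * field_width_um, 0.75 * field_width_um),
            rng.uniform(0.25 * field_height_um, 0.75 * field_height_um)]))

    def clip(pos: np.ndarray) -> np.ndarray:
        half = box_size_um / 2.0
        return np.clip(pos, [half, half],
                       [field_width_um - half, field_height_um - half])

    rows: List[CellTableRow] = []

    def add(pos: np.ndarray, phenotype: str) -> None:
        x, y = clip(pos)
        half = box_size_um / 2.0
        rows.append(CellTableRow(x - half, x + half, y - half, y + half,
                                 phenotype))

    for _ in range(n_cancer):
        c = clump_centers[rng.integers(len(clump_centers))]
        add(c + rng.normal(0.0, clump_sigma_um, 2), "PCK+")
    margin_radius = 1.5 * clump_sigma_um
    for phenotype, n in (("CD3+CD8+", n_effector), ("CD3+CD4+FOXP3+", n_regulatory)):
        for _ in range(n):
            if rng.random() < clustering:
                c = clump_centers[rng.integers(len(clump_centers))]
                ang = rng.uniform(0.0, 2.0 * np.pi)
                rad = abs(rng.normal(margin_radius, 0.25 * clump_sigma_um))
                add(c + rad * np.array([np.cos(ang), np.sin(ang)]), phenotype)
            else:
                add(rng.uniform([0.0, 0.0], [field_width_um, field_height_um]),
                    phenotype)
    return rows
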