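"""Replicate experiment runner and outcome analytics.

A configured experiment runs ``replicates`` independent stochastic
simulations of the same initial slide, each for up to 15 weeks (2520 hourly
steps) or until the cancer population reaches zero, and summarizes them as:

* **TE**, the tumor-eradication probability: the fraction of replicates whose
  cancer population hits zero by the horizon;
* the distribution of clearance times;
* per-replicate attribution of cancer deaths to mechanism (spontaneous
  apoptosis, effector-cell kill, radiation) over the 7-day and 1-day windows
  ending at clearance, which identifies the *primary* death mechanism of each
  responding replicate.

Immune recruitment-rate sets can be drawn by Latin Hypercube Sampling over
configurable bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from . import mihc
from .dynamics import (CycleParams, MotionParams, SimulationState,
                       advance_timestep)
from .mihc import InitialState, PhenotypeMap, generate_synthetic_slide
from .radiation import RadiosensitivityParams, TreatmentSchedule, make_schedule
from .recruitment import RecruitmentRates

__all__ = [
    "SlideConfig",
    "TreatmentConfig",
    "SimulationConfig",
    "Trajectory",
    "MechanismAttribution",
    "OutcomeSummary",
    "build_state",
    "simulate",
    "run_replicates",
    "tumor_eradication_probability",
    "mechanism_attribution",
    "compare_mechanisms",
    "summarize",
    "lhs_sample",
]

HOURS_PER_WEEK = 168
DEFAULT_HORIZON_H = 15 * HOURS_PER_WEEK  # 7 weeks of Tx + 8 weeks follow-up

LHS_PARAMETERS = ("zeta_apoptosis", "zeta_effector", "mu", "zeta_regulatory")
DEFAULT_LHS_BOUNDS: Dict[str, Tuple[float, float]] = {
    p: (0.0, 1.0) for p in LHS_PARAMETERS}


@dataclass
class SlideConfig:
    """Initial-condition source: a HALO CSV path or a synthetic slide."""

    path: Optional[str] = None
    n_cancer: int = 1000
    n_effector: int = 50
    n_regulatory: int = 25
    clustering: float = 0.5
    seed: int = 0


@dataclass
class TreatmentConfig:
    kind: str = "none"  # none | wtrt | grid30 | grid50 | custom
    weeks: int = 7
    peak_dose: float = 2.0
    dose_hour: int = 0
    valley_fraction: float = 0.15
    match_open_fraction: bool = True
    custom_fractions: Optional[List[Tuple[int, float]]] = None


@dataclass
class SimulationConfig:
    """All parameter blocks of one experiment; every default overridable."""

    width: int = 68
    height: int = 51
    node_pitch: float = 20.0
    kappa: float = 20.0
    dt_hours: float = 1.0
    horizon_hours: int = DEFAULT_HORIZON_H
    replicates: int = 50
    base_seed: int = 0
    slide: SlideConfig = field(default_factory=SlideConfig)
    motion: MotionParams = field(default_factory=MotionParams)
    cycle: CycleParams = field(default_factory=CycleParams)
    rates: RecruitmentRates = field(default_factory=RecruitmentRates)
    radio: RadiosensitivityParams = field(default_factory=RadiosensitivityParams)
    treatment: TreatmentConfig = field(default_factory=TreatmentConfig)

    def __post_init__(self) -> None:
        if self.horizon_hours <= 0:
            raise ValueError("horizon_hours must be positive")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def build_schedule(self) -> TreatmentSchedule:
        t = self.treatment
        return make_schedule(t.kind, weeks=t.weeks, peak_dose=t.peak_dose,
                             dose_hour=t.dose_hour, width=self.width,
                             height=self.height,
                             valley_fraction=t.valley_fraction,
                             match_open_fraction=t.match_open_fraction,
                             custom=t.custom_fractions)

    def load_initial_state(self) -> InitialState:
        if self.slide.path is not None:
            rows = mihc.read_cell_table(self.slide.path)
        else:
            rows = generate_synthetic_slide(
                self.slide.n_cancer, self.slide.n_effector,
                self.slide.n_regulatory, self.slide.clustering,
                self.slide.seed)
        from .lattice import LatticeDomain
        dom = LatticeDomain(self.width, self.height, self.node_pitch)
        return mihc.build_initial_state(rows, PhenotypeMap(), self.kappa, dom)


@dataclass
class Trajectory:
    """Per-hour population counts and death ledger of one replicate.

    Arrays share length ``T + 1`` and are indexed by hour; the death columns
    at index ``h`` count events during the step ending at hour ``h`` (index 0
    is all zeros).
    """

    hours: np.ndarray
    c: np.ndarray
    e: np.ndarray
    r: np.ndarray
    d_apoptosis: np.ndarray
    d_effector: np.ndarray
    d_radiation: np.ndarray
    mitoses: np.ndarray
    cleared: bool
    clearance_hour: Optional[int]
    replicate: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "hour": self.hours, "C": self.c, "E": self.e, "R": self.r,
            "deaths_apoptosis": self.d_apoptosis,
            "deaths_effector": self.d_effector,
            "deaths_radiation": self.d_radiation,
            "mitoses": self.mitoses,
        })

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def build_state(initial: InitialState, config: SimulationConfig,
                rng: np.random.Generator) -> SimulationState:
    """Materialize an initial slide as a live simulation state.

    Cancer agents sample a truncated-normal cycle length and a uniform
    position in the first half of their cycle; immune agents start with a
    clean hit ledger.
    """
    state = SimulationState(config.width, config.height, config.node_pitch)
    cp = config.cycle
    a = (cp.lo - cp.mean) / cp.sd
    b = (cp.hi - cp.mean) / cp.sd
    tn = stats.truncnorm(a, b, loc=cp.mean, scale=cp.sd)
    for (x, y), klass in initial.entries:
        if klass == "cancer":
            div = float(tn.rvs(random_state=rng))
            pos = rng.uniform(0.0, div / 2.0)
            state.add_agent("cancer", x, y, div_length=div, cycle_pos=pos)
        else:
            state.add_agent(klass, x, y)
    return state


def simulate(initial: InitialState, config: SimulationConfig,
             replicate: int = 0,
             schedule: Optional[TreatmentSchedule] = None) -> Trajectory:
    """Run one replicate to clearance or the horizon.

    Replicate ``k`` derives all its randomness from
    ``SeedSequence([base_seed, k])``, so runs are reproducible and replicates
    independent.
    """
    ss = np.random.SeedSequence([config.base_seed, replicate])
    kernel_seed = int(ss.generate_state(1, np.uint32)[0])
    rng = np.random.default_rng(ss)
    if schedule is None:
        schedule = config.build_schedule()
    state = build_state(initial, config, rng)
    state.seed_kernel(kernel_seed)
    rates = replace(config.rates)  # private accumulators per replicate

    c0, e0, r0 = state.counts()
    cs, es, rs = [c0], [e0], [r0]
    da, de, dr, dm = [0], [0], [0], [0]
    while state.hour < config.horizon_hours and cs[-1] > 0:
        row = advance_timestep(state, config.motion, config.cycle, rates,
                               config.radio, schedule, rng)
        c, e, r = state.counts()
        cs.append(c)
        es.append(e)
        rs.append(r)
        da.append(row.c_apoptosis)
        de.append(row.c_effector)
        dr.append(row.c_tx)
        dm.append(row.c_mitosis)
    carr = np.array(cs)
    cleared_at = np.flatnonzero(carr == 0)
    cleared = cleared_at.size > 0
    return Trajectory(np.arange(len(cs)), carr, np.array(es), np.array(rs),
                      np.array(da), np.array(de), np.array(dr), np.array(dm),
                      cleared, int(cleared_at[0]) if cleared else None,
                      replicate)


def run_replicates(config: SimulationConfig,
                   initial: Optional[InitialState] = None) -> List[Trajectory]:
    """Run all configured replicates from a shared initial slide."""
    if initial is None:
        initial = config.load_initial_state()
    schedule = config.build_schedule()
    if initial.counts()["cancer"] == 0 and not initial.entries:
        pass  # an empty slide is legal: every replicate clears at hour 0
    return [simulate(initial, config, k, schedule)
            for k in range(config.replicates)]


def tumor_eradication_probability(trajectories: Sequence[Trajectory]) -> float:
    """Cleared replicates / total replicates."""
    if not trajectories:
        raise ValueError("need at least one trajectory")
    return sum(t.cleared for t in trajectories) / len(trajectories)


@dataclass
class MechanismAttribution:
    """Cancer-death totals by mechanism over a clearance-anchored window."""

    apoptosis: int
    effector: int
    radiation: int
    window_hours: int
    primary: Optional[str]          # None when tied
    tied: Tuple[str, ...] = ()

    def totals(self) -> Dict[str, int]:
        return {"apoptosis": self.apoptosis, "effector": self.effector,
                "radiation": self.radiation}


def mechanism_attribution(traj: Trajectory,
                          window: int) -> Optional[MechanismAttribution]:
    """Death-mechanism totals in the ``window`` hours up to clearance.

    The window ends at (and includes) the clearance timestep and is truncated
    at hour 0 for early clearances.  Returns ``None`` for replicates that did
    not clear (they have no clearance anchor); ties for the primary mechanism
    are reported, not silently broken.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not traj.cleared or traj.clearance_hour is None:
        return None
    ch = traj.clearance_hour
    lo = max(0, ch - window + 1)
    sl = slice(lo, ch + 1)
    totals = {
        "apoptosis": int(traj.d_apoptosis[sl].sum()),
        "effector": int(traj.d_effector[sl].sum()),
        "radiation": int(traj.d_radiation[sl].sum()),
    }
    top = max(totals.values())
    winners = tuple(k for k, v in totals.items() if v == top)
    primary = winners[0] if len(winners) == 1 else None
    return MechanismAttribution(totals["apoptosis"], totals["effector"],
                                totals["radiation"], window, primary, winners)


def compare_mechanisms(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p-value between per-replicate mechanism totals
    (exact Mann-Whitney for small samples, normal approximation otherwise)."""
    method = "exact" if min(len(x), len(y)) <= 25 else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


@dataclass
class OutcomeSummary:
    te: float
    n_replicates: int
    n_cleared: int
    clearance_hours: List[int]
    attribution: Dict[int, List[MechanismAttribution]]

    def to_dict(self) -> dict:
        return {
            "te": self.te,
            "n_replicates": self.n_replicates,
            "n_cleared": self.n_cleared,
            "clearance_hours": self.clearance_hours,
            "attribution": {
                str(w): [a.totals() | {"primary": a.primary} for a in lst]
                for w, lst in self.attribution.items()},
        }


def summarize(trajectories: Sequence[Trajectory],
              windows: Sequence[int] = (168, 24)) -> OutcomeSummary:
    te = tumor_eradication_probability(trajectories)
    cleared = [t for t in trajectories if t.cleared]
    attribution = {
        int(w): [a for a in (mechanism_attribution(t, w) for t in cleared)
                 if a is not None]
        for w in windows}
    return OutcomeSummary(te, len(trajectories), len(cleared),
                          [int(t.clearance_hour) for t in cleared], attribution)


def lhs_sample(n_sets: int,
               bounds: Optional[Dict[str, Tuple[float, float]]] = None,
               seed: int = 0, zeta_tx: float = 0.0) -> List[RecruitmentRates]:
    """Latin Hypercube sample of the four immune recruitment parameters.

    Each parameter's ``n_sets`` values occupy its ``n_sets`` equal-width
    strata exactly once (uniform within stratum, independently permuted
    across parameters); deterministic for a fixed seed.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    bounds = dict(DEFAULT_LHS_BOUNDS, **(bounds or {}))
    lo = np.array([bounds[p][0] for p in LHS_PARAMETERS])
    hi = np.array([bounds[p][1] for p in LHS_PARAMETERS])
    if np.any(lo >= hi):
        raise ValueError("each lower bound must be below its upper bound")
    sampler = qmc.LatinHypercube(d=len(LHS_PARAMETERS), seed=seed)
    unit = sampler.random(n_sets)
    scaled = qmc.scale(unit, lo, hi)
    return [RecruitmentRates(zeta_apoptosis=float(row[0]),
                             zeta_effector=float(row[1]),
                             mu=float(row[2]),
                             zeta_regulatory=float(row[3]),
                             zeta_tx=zeta_tx)
            for row in scaled]
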