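# Methods

## Model overview and assumptions

`gridabm` simulates a 2D tissue section as a 68 × 51 lattice of 20 µm square
nodes (the assumed mean cell diameter), each holding at most one agent, with
an hourly timestep. The domain is closed — no flux across the boundary, no
wraparound — because it represents a fixed biopsy-sized patch of tumor, not
a periodic medium. All radius-type queries (target search, GRID openings,
post-code placement) use the Euclidean metric on node indices; Euclidean
distance is the natural choice for circular collimator openings and makes
disk queries rotation-consistent.

Three agent classes interact: cancer cells, anti-tumor effector cells
(cytotoxic CD8⁺ proxy) and pro-tumor regulatory cells (Treg proxy). The
model deliberately collapses the cellular and molecular detail of the tumor
immune microenvironment — chemokine fields, vasculature, dendritic-cell
trafficking, antigen presentation — into a small set of per-hour rates and
a target-seeking migration rule. It is a hypothesis-generating model of
*relative* treatment behavior, not a calibrated predictor for any cancer
type.

## The hourly update

Each hour advances in a fixed phase order:

1. **Recruitment** — immune cells earned by the *previous* hour's ledger are
   placed (see below).
2. **Irradiation** — if a fraction is scheduled this hour, every agent draws
   survival against its node's dose.
3. **Agent steps** — all live agents are shuffled uniformly and stepped one
   at a time. Shuffling removes raster-order artifacts (e.g., a growth bias
   toward the upper-left) that fixed sweep orders produce in single-occupancy
   automata. Agents born during the phase do not act until the next hour,
   and a freed lattice slot is never reused within the phase.
4. **Hit resolution** — targets that accumulated ≥3 hits this hour die;
   anything less repairs completely (hit counters reset).
5. **Ledger close** — per-mechanism death counts and kill locations become
   the input for next hour's recruitment; population counts are recorded.

### Cancer cells

In order: a cell doomed by radiation whose 8 h delay has elapsed is removed
(counted as a radiation death at the removal hour); otherwise it dies with
probability p_a = 3×10⁻³ per hour (node freed immediately; mean lifetime
1/p_a ≈ 13.9 days); otherwise it advances its cell cycle by 1 h if any Moore
neighbor is vacant (contact inhibition: fully surrounded cells are quiescent
this hour); on completing its cycle with a vacancy available and while not
doomed, it divides — the daughter takes a uniformly random vacant Moore node
and samples a fresh cycle length; finally, with probability p_m = 0.9 it
performs up to 6 single-node moves to random vacant Moore nodes (6 nodes/h ≡
2.3 µm/min at 20 µm pitch). One Bernoulli(p_m) draw gates the whole 6-move
walk, which reads the "probability of migration per timestep" and the
"up to 6 moves per timestep" statements as one decision followed by an
iterated walk.

Cycle lengths are truncated-normal: mean 24 h, SD 2 h, bounds [18, 30] h
(SD and bounds are package choices — a few-hour spread around the canonical
24 h cycle — and configurable). At initialization each cancer cell starts
uniformly within the first half of its cycle.

### Immune cells

An immune cell performs 15 sub-moves per hour (15 nodes/h ≡ 5 µm/min).
Each sub-move: find the nearest target within 50 nodes (effectors target
cancer cells; regulatory cells target effectors), breaking distance ties
uniformly; with no target in range, move to a random vacant Moore node.
Otherwise combine a fresh random unit vector v with the unit bearing u to
the target as w = (1 − η)v + ηu, η = 0.19, and move into the vacant Moore
node whose direction minimizes the angle to w (exact cosine comparison,
ties uniform; stay put if boxed in). After all sub-moves the cell delivers
at most one hit to one uniformly chosen adjacent target of its class. Three
hits on one target within a single hour kill it; an immune cell that has
delivered 10 lifetime hits is exhausted and removed. Immune cells have no
spontaneous death in the default configuration — exhaustion and radiation
are their only exits — matching the minimal rule set; a lifespan hook can
be added via the death-hour field if a calibration requires one.

Interaction strictly follows the full sub-move sequence (not interleaved
with it), reading "following attempted or successful migration … it can
interact" as move-then-hit.

Cells doomed by radiation keep occupying their node during the 8 h lag,
cannot divide, still migrate, and can still be killed by effectors (then
counted as effector kills) — dying cells remain physical obstacles and
antigen sources until cleared.

### Recruitment

Per channel, recruits(t+1) = rate × events(t), accumulated with a
floor-with-carry rule: the integer part is placed, the fractional part
carries to the next hour, so long-run recruitment matches rate × events to
within one cell deterministically (an alternative Bernoulli rounding would
add variance without adding realism). Apoptosis-, radiation- and
mitosis-driven recruits land on uniformly random vacant nodes (uniform
blood-vessel assumption). Each effector-kill-driven recruit homes, with
probability µ, to a uniformly random vacant node within 10 nodes of a
uniformly chosen previous-hour kill site (post-code homing); if that disk
is full it falls back to global placement rather than being lost; with
probability 1 − µ it places globally. Recruits that find no vacancy
anywhere are discarded and counted.

### Radiation

Survival follows SF_i(d) = exp(−α_i d/ξ − β_i (d/ξ)²). Only the 2 Gy
surviving fraction of each class is calibrated — 0.49 (cancer), 0.60
(effector), 0.77 (regulatory) — so (α, β) is recovered by fixing the α/β
ratio: 10 Gy for cancer (typical rapidly proliferating tumor) and 3 Gy for
immune cells (late-responding normal tissue). At 2 Gy per fraction the
split barely matters because SF(2 Gy) is pinned by construction; both
ratios are configurable. ξ = 1 for actively cycling cancer cells (not
quiescent last hour, not doomed) and ξ = 3 for quiescent ones, making
crowded tumor cores markedly more resistant (SF ≈ 0.81 at 2 Gy). Immune
agents do not cycle in this model and are irradiated at ξ = 1; their
calibrated SF(2 Gy) values already encode their overall sensitivity.

Kill is not immediate: non-survivors are removed 8 h after the fraction
(mitotic-catastrophe delay), and the radiation-death ledger therefore feeds
ζ_Tx recruitment in the hour after removal, not the hour of irradiation.
Surviving cycling cancer cells lengthen their current cycle by 2 h per Gy
of *nominal* node dose (the repair-delay statement references administered
dose, so the quiescence divisor is not applied here).

### Dose geometry and scheduling

WTRT delivers a spatially uniform 2 Gy per weekday (Mon–Fri) fraction for
7 weeks — 35 fractions, 70 Gy. GRID blocks tile circular openings on a
square lattice of centers anchored at the domain midpoint; nodes within the
opening radius (inclusive) receive the peak dose and all others receive
15% of it (valley fraction 0.15; this value, not a peak-to-valley ratio of
15, is what reproduces the 0.81 / 1.15 Gy mean fraction doses at 30% / 50%
open). The block never moves between fractions (perfect inter-fraction
alignment; dose smearing is out of scope).

Literal 11-node-diameter openings at 30- or 35-node spacing cover only
~11% / 8% of the domain — a circle of diameter 11 simply cannot fill 30%
of a 30 × 30 tile — so by default the `grid30` / `grid50` schedules solve
the opening diameter against the *realized* open-node fraction on the
actual 68 × 51 window (≈19 and ≈30 nodes respectively), hitting the stated
30% / 50% open-to-shielded splits to within 0.5%. The literal geometry
remains available (`match_open_fraction=False`) and every dose map reports
its realized open fraction. Arbitrary custom (hour, dose) schedules — e.g.
a single 15 Gy ablative fraction — are supported.

## Initialization from cell tables

HALO-style tables give per-cell bounding boxes in µm and a phenotype label.
Box centers map to nodes by floor(center/κ), κ = 20 µm. Cells colliding on
one node keep the first row in file order (the table order is the only
deterministic, data-independent rule available; the dropped count is
reported), which makes the retained fraction monotonically non-increasing
in κ. The default phenotype reduction sends PCK⁺ → cancer, CD3⁺CD8⁺ →
effector, CD3⁺CD4⁺FOXP3⁺ → regulatory, and parks CD68⁺ macrophages and
FOXP3⁻ helpers outside the three-class model ("ignore"; excluded from the
retention denominator). The mapping is a documented default, configurable
per dataset.

## Synthetic slides

The generator emulates a 1360 × 1020 µm biopsy field: cancer cells drawn
from one (or more) Gaussian clumps (σ = 250 µm, centered in the field),
immune cells split between uniform scatter (weight 1 − clustering) and a
ring around the tumor margin at ≈1.5σ (weight clustering). Default
composition — 1000 cancer, 50 effector, 25 regulatory cells, clustering
0.5 — depicts a moderately infiltrated tumor; after κ-mapping collisions it
yields ≈790 cancer agents on the lattice. Varying the counts and
clustering spans immune-desert to inflamed microenvironments.

What the generator does *not* emulate: realistic marker noise and
segmentation artifacts, stromal architecture and tissue folds, multi-focal
phenotype gradients, or the empirical cell-density profiles of real slides.
Tests passing on synthetic slides therefore validate the simulator's
mechanics and bookkeeping, not any claim about real patient tissue.

## Randomness and reproducibility

Replicate k of an experiment derives everything from SeedSequence([base_seed,
k]): one 32-bit seed for the compiled stepping kernel's random stream
(agent shuffling, per-agent fate draws, tie-breaks) and one numpy Generator
for the orchestration layer (initial property sampling, survival draws at
irradiation, recruit placement). Two named streams instead of one is a
concession to the compiled kernel; replays are bitwise identical and
replicates independent. Latin Hypercube sampling (scipy's implementation)
stratifies each of the four recruitment parameters into n equal-width bins
used exactly once, uniform within bin, deterministically per seed.

## Numerical and degenerate-input choices

* Angle minimization uses exact floating-point cosine comparison; exact
  ties (symmetric geometries) are broken uniformly.
* Distance ties in target search are exact in integer squared distance.
* survival-fraction calibration requires SF(2 Gy) ∈ (0, 1]; SF = 1 maps to
  α = β = 0 (radioresistant limit). valley_fraction = 1 degenerates a GRID
  map to WTRT.
* A tumor-free initial slide is a warning, not an error; every replicate
  then clears at hour 0.
* Recruits with no vacancy anywhere (saturated lattice) are discarded and
  counted, never queued.
* The agent arrays reserve twice the node count so that births within one
  phase can never recycle a slot freed earlier in the same phase.

## Default recruitment rates

The four baseline rates ship as ζ_apoptosis = 0.2, ζ_effector = 0.4,
µ = 0.5, ζ_regulatory = 0.2 (ζ_Tx defaults to 0), chosen once as a
mid-range, immune-escape-regime set: untreated tumors under these defaults
grow to lattice saturation past the immune response, which is the
clinically relevant baseline for a detectable tumor (a parameter set whose
tumors clear untreated would model a lesion that never presents). LHS
sweeps over [0, 1]⁴ are the supported way to explore alternatives.

## Problem sizes used in the shipped experiments

The package's experiment-level checks run 20 replicates per arm on the
default synthetic slide over the full 15-week horizon (2520 hourly steps,
up to ~3500 agents), which is sufficient to resolve the qualitative
treatment contrast (a 1-SE tolerance on TE differences at n = 20); the
Monte-Carlo survival checks use 10⁵ agents (binomial SE ≈ 0.0016), and the
apoptosis-lifetime check 10⁴ agents. A full 2520-hour replicate takes
roughly 5–10 s on one core once the kernels are compiled.

## Known limitations

* Continuous chemokine gradients are abstracted into the nearest-target
  rule; there is no diffusible field, so immune cells ignore targets beyond
  50 nodes entirely.
* With all recruitment rates ≤ 1 and the 10-hit exhaustion rule, effector
  populations are strongly turnover-limited and three-hits-in-one-hour
  coincidences are rare at moderate densities; immune-mediated clearance
  of a large tumor requires either a strongly inflamed initial state or
  rates above the unit range. The package treats the rate bounds as data,
  not as a constant of nature — they are fully configurable.
* Single occupancy with no pushing means dense cores grow only through
  surface vacancies; growth is therefore interface-limited by construction.
* 2D only; no re-oxygenation, radiosensitization or inter-fraction geometry
  changes; no immune memory or antigen escape.
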