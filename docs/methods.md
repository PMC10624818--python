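# Methods

## Model and assumptions

Recovery is modeled as a deterministic complex contagion on an
undirected spatial contiguity graph. Two states per unit, *affected*
and *recovered*; recovered is absorbing. At each weekly synchronous
update a unit recovers when the fraction of its already-recovered
neighbors reaches its threshold τᵢ ∈ [0, 1]. The comparison is ≥, so a
tie recovers, and τᵢ = 0 units recover at the first update
unconditionally. The model assumes (a) the contiguity graph is static
over the study window, (b) recovery interdependence acts only through
first-order adjacency, and (c) a week is the natural update interval —
all inherited from the weekly resolution of the observed recovery
states.

Time runs t = 0..14 weeks with t = 0 the end of the hazard event and
everyone affected. The first update is applied at t = 2
(`DiffusionConfig.first_update_week`, overridable): with all units
affected through week 1, the zero-threshold cohort becomes the first
group recovered at the end of week 2, and the t = 1 term of the loss
is identically zero because no empirical recovery week is below 2
either. Whether updates should instead begin at t = 1 is not
observable from weekly data under this encoding; the convention is
recorded in the config rather than hard-coded.

Isolated units (empty neighborhood) have neighbor fraction 0 by
convention and therefore recover iff τᵢ = 0; they are retained in the
graph because upstream filtering (minimum visit counts) should remain
explicit, not implicit in graph construction.

## Contiguity construction

Queen/rook/bishop adjacency is decided from the dimension of the
pairwise geometric intersection after an optional coordinate snap
(default 0, i.e. exact): positive-length (or areal) contact is rook,
point-only contact is bishop, queen is their union. Candidate pairs
come from an STRtree bounding-box query, so construction is
near-linear in practice. Multipolygon units are neighbors if any part
touches. Invalid polygons are repaired (`make_valid`) or rejected by
unit id. The implementation is invariant to input order and satisfies
queen = rook ∪ bishop by construction of the dimension test; the test
suite asserts both on jittered lattices.

## Preprocessing

A unit's baseline is its mean daily visit count over a fixed pre-event
window (default Aug 1–21). Daily counts are smoothed by a centered
7-day moving average (3 days either side; edge days without a full
window are dropped). The unit recovers on the first day r, searched
from the week origin (default Aug 27), on which the smoothed series
holds at ≥ 90% of baseline for 3 consecutive days; duration in weeks
is (r − origin + 1)/7, so the earliest observable recovery is day 8 =
1.14 weeks. No qualifying day within the 14-week window ⇒ duration 14,
censored. The 3-day criterion is applied to the smoothed series, and
the 3 days are taken as consecutive. The minimum-visit filter drops
units whose *baseline-window mean* daily visits fall below 4 — the
published rule is ambiguous about the averaging window, and a
mean-based rule is deterministic and scale-free. Discretized week =
ceil(duration) clamped into {2..14}.

## Calibration (stage 1)

The GA is deliberately classical. Population η = 10 (even), fitness
1/L with a sentinel fitness of 2.0 for L = 0 (strictly above any
attainable reciprocal, so perfect chromosomes always rank first).
Selection keeps the two fittest chromosomes (ties by lower index) and
fills the remaining η − 2 parent slots by roulette wheel with
replacement; the elite pair passes to the next generation unmodified,
which makes the best-loss trace provably non-increasing, and the other
parents undergo single-point crossover at an interior point followed
by a single one-position mutation (keep with probability 0.5, else
resample Uniform[0,1]). Pinned-zero genes ride along in the chromosome
and are re-clamped to zero after every operator, keeping the codec
uniform. All randomness flows from one `numpy` Generator per run, so a
(config, seed) pair reproduces the run exactly.

Units observed recovering in under 2 weeks are pinned at τ = 0 before
calibration; they are the diffusion's seedbed. Thresholds are
identifiable only up to the interval between attainable neighbor
fractions — for a unit first recovered at week w, any τ in
(f_{w−2}, f_{w−1}] reproduces w, with f_t its recovered-neighbor
fraction at week t. Tests therefore assert interval membership
(`identifiable_intervals`), never point equality.

## Seed-set optimization (stage 2)

The same GA loop runs over a subset codec: a chromosome is a vector of
N distinct unit indices; single-point crossover is followed by a
repair step replacing duplicates with uniformly random non-members,
and mutation swaps one member for a random non-member with probability
0.5 (a no-op when N = n, where no non-member exists). The objective is
the number of still-affected units at the horizon with the chromosome
as the t = 0 seed set and the calibrated τ* held fixed. Zero-threshold
units are eligible multipliers — no exclusion is imposed. The
"without optimization" reference for the increment rate is the best
recovered count in the randomly initialized generation 0, which is why
it varies with N. Because the dynamics are monotone in the seed set,
the optimized count can never fall below that reference. On instances
with C(n, N) ≤ 10,000 the GA's optimum is checked against exhaustive
enumeration.

## Spatial diagnostics

Local Moran's I uses row-standardized contiguity weights:
Iᵢ = zᵢ · Σⱼ wᵢⱼ zⱼ with z the standardized field. Pseudo p-values
come from conditional permutation (default 999 draws, α = 0.05):
holding zᵢ fixed, neighbor values are resampled from the other n − 1
units, and the p-value is the one-sided rank of the observed Iᵢ on its
own sign side, (extreme + 1)/(permutations + 1). Quadrants HH/HL/LH/LL
are assigned from the signs of zᵢ and its spatial lag where p ≤ α;
`lisa_quadrants` gives labels without inference. A constant field has
undefined I and is reported all-not-significant. Labels are invariant
under positive affine rescaling of the field.

Convergence diagnostics: the cumulative mean of each probe unit's τ
across repeated calibrations, and for multiplier sets the cumulative
mean of N − |Mᵣ ∩ M₁| over runs r = 2..R against the run-1 reference —
a fixed reference keeps the series well-defined where a consensus set
would not be. Threshold moments use the population (1/n) variance,
pinned zeros included (configurable via `ddof`).

Disparity summaries report median and quartiles of median household
income, per-capita income and minority percentage inside vs outside
the multiplier set, plus the median difference; no inferential test is
attached, matching the descriptive intent.

## Synthetic data

The generator emulates the *structure* of a county-scale mobility
study: a rows × cols unit-square lattice (optionally jittered at the
shared corner grid, which preserves adjacency), a zero-threshold
cohort of 37% of units, free thresholds Uniform[0,1] (or Beta),
forward simulation to T = 14, and continuous durations week − u with
u ~ Uniform[0,1) floored at 1.14 weeks so discretization returns the
planted week. Visit series are piecewise-constant: baseline level
through the pre-event window, a drop to 20% of baseline three days
before the week origin, and a return to baseline three days before the
planted recovery day — with a 20% floor the smoothed series reaches
88.6% of baseline the day before recovery and 100% on it, so the 90%
rule fires exactly on the planted day. Censored units never rise.
Demographics draw incomes/minority shares from normal distributions
with a planted gap between the late-recovering half (duration above
the median) and the rest.

What the generator does **not** emulate: real county geometry (the
lattice is more regular, degree ≈ 7 vs ≈ 6), device-panel sampling
noise in visit counts (Poisson noise is available but off by default),
seasonal visitation trends, and any spatial correlation between
demographics and graph position beyond the recovery-time link. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of planted structure, not empirical adequacy on
licensed mobility data.

Default test scenario: 10 × 10 grid, zero-seed fraction 0.37, uniform
thresholds, zero noise — about a hundred units calibrate in seconds at
η = 10 while exercising every code path, including censored units.

## Numerical choices

* Ties in the threshold comparison recover (≥), matching the update
  rule's definition.
* The 0–1 loss sums t = 1..T; the seeded t = 0 column is excluded.
* Fitness sentinel for zero loss: 2.0.
* Crossover point excludes the ends, so offspring always mix.
* Half-up rounding maps percentage seed-set sizes to counts
  (5% of 2,010 → 101; floor of 1).
* Stage seeds derive from CRC32(stage name) XOR the global seed,
  modulo 2³¹, so stages are decorrelated but reproducible.
* The week-14 entry of the weekly difference report is annotated as
  censoring-inflated: units still affected at the window close are
  *coded* recovered at week 14 in empirical data, so the week-14 spike
  reflects the analysis window, not model error.

## Known limitations

* The GA is a metaheuristic: on duration-encoded (censored) data the
  final loss retains a floor of roughly one cell per censored unit,
  and convergence to the global optimum is only guaranteed in the
  tested small planted instances.
* Thresholds are set-identified (intervals), so run-to-run τ variation
  is expected; the convergence diagnostics exist precisely to monitor
  it.
* ESRI shapefile input is not supported; supply GeoJSON or an
  edge-list CSV.
* The GA performance index ΔL/R divides by wall-clock runtime per
  generation and is hardware-dependent; it is a tuning diagnostic,
  not a model quantity.
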