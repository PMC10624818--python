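# recovnet

Post-disaster community recovery modeled as a threshold-diffusion
process on a spatial contiguity network.

After a major disaster, neighborhoods do not recover in isolation: an
area's return to normal activity depends on the recovery of the areas
around it, because residents rely on neighboring businesses, services
and infrastructure. `recovnet` is for researchers in disaster
resilience, spatial epidemiology and urban analytics who want to

* measure per-unit **population-activity recovery durations** from
  daily point-of-interest (POI) visit counts,
* estimate the strength of **spatial recovery interdependence** for
  every unit, and
* identify **recovery multipliers** — the small set of areas whose
  early recovery most accelerates recovery of the whole community.

## The model

Spatial units (e.g. census block groups) are the vertices V of an
undirected graph G = (V, E) built by **queen contiguity** (units
sharing an edge or a vertex are neighbors; rook and bishop rules are
also available). Summary statistics are the average node degree
k = 2m/n and density d = 2m/(n(n−1)).

Each unit i is *affected* (state S⁽ⁱ⁾ = 0) at t = 0 and flips
irreversibly to *recovered* (state 1). With τᵢ ∈ [0, 1] the unit's
threshold and N(νᵢ) its neighbor set, the weekly synchronous update is

    S_{t+1}^{(i)} = 1   if   Σ_{j∈N(νᵢ)} S_t^{(j)} / #N(νᵢ)  ≥  τᵢ,

run from week 2 (units with τᵢ = 0 form the first recovered cohort)
through the horizon T = 14 weeks. A high τᵢ means the unit recovers
only when most of its neighborhood has — a strong spatial effect.

**Stage 1 (calibration).** Observed recovery durations are discretized
to weeks and encoded as a binary unit × week matrix S. A classical
genetic algorithm (fitness 1/L, elitist selection, single-point
crossover, one-position 50% mutation) searches for the threshold
vector τ* minimizing the 0–1 loss

    L(S, Ŝ) = Σ_{t=1..14} Σ_{i=1..n} I(S_t^{(i)} ≠ Ŝ_t^{(i)}),

where Ŝ is the simulated trajectory. Units recovering in under two
weeks are pinned at τᵢ = 0.

**Stage 2 (recovery multipliers).** With τ* fixed, the same GA
searches over seed sets Mᴺ of exactly N units marked recovered at
t = 0, maximizing the recovered count at t = 14. The benefit is
reported as the increment rate
100 · (recovered_with − recovered_without) / recovered_without.

Diagnostics include local Moran's I (LISA) classification of the
threshold field (HL: high threshold amid low-threshold neighbors; LH:
the converse), run-to-run convergence of thresholds and multiplier
sets, and income/minority disparity summaries of the multiplier set.

## Worked example

Licensed mobility data is not required: the synthetic generator plants
a full ground truth (thresholds, trajectory, visit series,
demographics) on a polygon lattice and writes the same file formats
the real pipeline reads.

```
$ recovnet synth --rows 10 --cols 10 --seed 0 --out demo
wrote synthetic scenario (100 units, 342 edges) to demo

$ recovnet graph --geojson demo/units.geojson --out demo
{"n": 100, "m": 342, "avg_degree": 6.84, "density": 0.0691}

$ recovnet calibrate --edgelist demo/edges.csv --durations demo/durations.csv \
      --eta 10 --max-generations 3000 --seed 1 --out demo/calib
{"final_loss": 17, "initial_loss": 175.0}

$ recovnet multipliers --edgelist demo/edges.csv --tau demo/calib/tau_star.csv \
      --n 5 --seed 1 --max-generations 500 --out demo/multipliers.csv
{"N": 5, "recovered_at_T": 98, "baseline_recovered": 87, "increment_pct": 12.64}

$ recovnet lisa --edgelist demo/edges.csv --tau demo/calib/tau_star.csv \
      --seed 0 --out demo/lisa.csv
{"ns": 94, "HH": 5, "LH": 1}
```

Reading the numbers: the 10×10 queen lattice has average degree 6.84.
Calibration drives the 0–1 loss from 175 disagreeing unit-week cells
in the random initial population down to 17 (residual cells are mostly
units right-censored at 14 weeks, whose empirical coding marks them
recovered at the window close). Seeding the 5 best multiplier units
raises the week-14 recovered count from 87 (best random seed set) to
98, a 12.64% increment. LISA flags 5 significant high-high threshold
clusters and 1 low-high unit at α = 0.05.

The full pipeline (`recovnet all --config run.yaml --seed 0 --out out/`)
chains preprocessing, graph construction, the randomized baseline, both
optimization stages, LISA and the disparity summary, and writes a
manifest that reproduces any stage bit-for-bit.

The same steps are available as a library:

```python
from recovnet import (SyntheticScenario, build_scenario,
                      calibrate_thresholds, GAConfig)
_, graph, truth = build_scenario(SyntheticScenario(rows=10, cols=10, rng_seed=0))
result = calibrate_thresholds(graph, truth.trajectory, truth.zero_mask,
                              GAConfig(10, 5000, rng_seed=1))
print(result.final_loss)   # 0 — the planted model is recovered exactly
```

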