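"""Two-stage optimization of the recovery diffusion model.

Stage 1 calibrates the per-unit thresholds: a GA searches the
[0,1]^n threshold space (units in the early-recovery cohort pinned to
zero) for the vector whose simulated trajectory minimizes the 0-1 loss
against the empirically observed weekly recovery states.

Stage 2 takes the calibrated thresholds as fixed and searches for the
set of N "recovery multipliers" — units marked recovered at t = 0 —
that maximizes the community-wide recovered count at the horizon. The
benefit of an optimized set is summarized by the increment rate
100 * (recovered_with - recovered_without) / recovered_without.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .diffusion import (
    DiffusionConfig,
    DiffusionEngine,
    StateTrajectory,
    ThresholdVector,
    loss,
)
from .ga import Chromosome, GAConfig, GATrace, RealVectorCodec, SubsetCodec, run_ga
from .spatial import ContiguityGraph

__all__ = [
    "CalibrationResult",
    "MultiplierSet",
    "calibrate_thresholds",
    "optimize_multipliers",
    "exhaustive_multipliers",
    "increment_rate",
    "affected_at_horizon",
    "identifiable_intervals",
]


@dataclass
class CalibrationResult:
    """Stage-1 output: calibrated thresholds and their fit."""

    tau_star: ThresholdVector
    final_loss: int
    trace: GATrace
    simulated: StateTrajectory


@dataclass
class MultiplierSet:
    """Stage-2 output: the optimized seed set of size N."""

    N: int
    members: set[str]
    recovered_at_T: int
    baseline_recovered: int
    trace: GATrace | None = None

    def __post_init__(self) -> None:
        if len(self.members) != self.N:
            raise ValueError("multiplier set size must equal N")


def calibrate_thresholds(
    graph: ContiguityGraph,
    empirical: StateTrajectory,
    zero_mask: np.ndarray,
    cfg: GAConfig,
    dcfg: DiffusionConfig = DiffusionConfig(),
) -> CalibrationResult:
    """Stage 1: fit the threshold vector to the empirical trajectory.

    zero_mask marks the units whose observed recovery preceded week 2;
    their thresholds are pinned at zero, making them the first cohort
    to recover (at the end of week ``dcfg.first_update_week``) and the
    seedbed from which the diffusion propagates.
    """
    if empirical.n != graph.n:
        raise ValueError("empirical trajectory does not align with the graph")
    if empirical.horizon != dcfg.T:
        raise ValueError("empirical horizon does not match the diffusion config")
    zero_mask = np.asarray(zero_mask, dtype=bool)
    engine = DiffusionEngine(graph, dcfg)
    emp = empirical.states[:, 1:]

    def objective(genes: np.ndarray) -> float:
        sim = engine.simulate(genes)
        return int((emp != sim.states[:, 1:]).sum())

    codec = RealVectorCodec(graph.n, zero_mask=zero_mask)
    best, trace = run_ga(objective, codec, cfg)
    tau_star = ThresholdVector(best.genes, fixed_zero_mask=zero_mask)
    simulated = engine.simulate(tau_star)
    return CalibrationResult(tau_star, int(best.loss), trace, simulated)


def optimize_multipliers(
    graph: ContiguityGraph,
    tau_star: ThresholdVector,
    N: int,
    cfg: GAConfig,
    dcfg: DiffusionConfig = DiffusionConfig(),
) -> MultiplierSet:
    """Stage 2: GA search over size-N seed sets maximizing the
    recovered count at the horizon; thresholds stay fixed.

    baseline_recovered is the best objective in the randomly
    initialized generation 0 — the "no optimization" reference the
    increment rate is computed against.
    """
    if N > graph.n:
        raise ValueError("N cannot exceed the number of units")
    engine = DiffusionEngine(graph, dcfg)
    vertices = graph.vertices
    if N == 0:
        rec = engine.final_recovered(tau_star)
        return MultiplierSet(0, set(), rec, rec)

    def objective(genes: np.ndarray) -> float:
        # minimized loss = units still affected at the horizon
        seeds = np.zeros(graph.n, dtype=bool)
        seeds[np.asarray(genes, int)] = True
        return graph.n - engine.final_recovered(tau_star, seeds)

    codec = SubsetCodec(graph.n, N)
    best, trace = run_ga(objective, codec, cfg)
    members = {vertices[int(i)] for i in best.genes}
    recovered = graph.n - int(best.loss)
    baseline = graph.n - int(trace.best_loss[0])
    return MultiplierSet(N, members, recovered, baseline, trace)


def exhaustive_multipliers(
    graph: ContiguityGraph,
    tau_star: ThresholdVector,
    N: int,
    dcfg: DiffusionConfig = DiffusionConfig(),
    max_combinations: int = 10_000,
) -> tuple[set[str], int]:
    """Brute-force oracle over all C(n, N) seed sets; only feasible on
    small instances. Returns the best set and its recovered count."""
    n = graph.n
    if math.comb(n, N) > max_combinations:
        raise ValueError("instance too large for exhaustive enumeration")
    engine = DiffusionEngine(graph, dcfg)
    best_set, best_rec = set(), -1
    for combo in itertools.combinations(range(n), N):
        seeds = np.zeros(n, dtype=bool)
        seeds[list(combo)] = True
        rec = engine.final_recovered(tau_star, seeds)
        if rec > best_rec:
            best_rec = rec
            best_set = {graph.vertices[i] for i in combo}
    return best_set, best_rec


def increment_rate(recovered_without: int, recovered_with: int) -> float:
    """100 * (with - without) / without, rounded to 2 decimals."""
    if recovered_without <= 0:
        raise ValueError("recovered_without must be positive")
    return round(100.0 * (recovered_with - recovered_without) / recovered_without, 2)


def affected_at_horizon(S: StateTrajectory) -> int:
    """Units still affected at the final week of the trajectory."""
    return S.n - S.recovered_at(S.horizon)


def identifiable_intervals(
    graph: ContiguityGraph,
    empirical: StateTrajectory,
    dcfg: DiffusionConfig = DiffusionConfig(),
) -> list[tuple[float, float]]:
    """Per-unit interval (lo, hi] of thresholds consistent with the
    empirical trajectory, assuming the trajectory is self-consistent
    (reproducible by some threshold vector).

    A unit first recovered at week w has  f_{w-2} < tau <= f_{w-1},
    where f_t is its recovered-neighbor fraction at the end of week t
    in the empirical trajectory; a never-recovered unit needs
    tau > f_{T-1}. Thresholds are identifiable only up to these
    intervals — attainable neighbor fractions are discrete.
    """
    engine = DiffusionEngine(graph, dcfg)
    states = empirical.states.astype(float)
    fracs = (engine.adj @ states) / engine._safe_deg[:, None]  # (n, T+1)
    weeks = empirical.recovery_weeks()
    out: list[tuple[float, float]] = []
    for i in range(graph.n):
        w = int(weeks[i])
        if w > empirical.horizon:  # never recovered in-window
            out.append((float(fracs[i, empirical.horizon - 1]), 1.0))
        else:
            # the lower bound "not yet recovered at week w-1" only binds
            # once updates have started; before that any tau <= hi works
            lo = float(fracs[i, w - 2]) if w > dcfg.first_update_week else -1.0
            hi = float(fracs[i, w - 1])
            out.append((lo, hi))
    return out
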