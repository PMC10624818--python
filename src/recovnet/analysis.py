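"""Spatial diagnostics for calibrated thresholds and multiplier sets.

* Local Moran's I (LISA) with conditional-permutation pseudo p-values
  and HH/HL/LH/LL quadrant labels — used to find units whose recovery
  threshold is high amid low-threshold neighbors (HL) and vice versa
  (LH).
* Run-to-run convergence diagnostics: cumulative-mean threshold series
  per probe unit and cumulative-mean multiplier-set differences.
* Sociodemographic disparity summaries for multiplier vs
  non-multiplier units.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffusion import ThresholdVector
from .spatial import ContiguityGraph
from .twostage import MultiplierSet

__all__ = [
    "LisaResult",
    "local_morans",
    "threshold_convergence",
    "multiplier_set_stability",
    "disparity_summary",
    "threshold_moments",
    "read_demographics_csv",
]

DEMOGRAPHIC_ATTRS = ("median_household_income", "per_capita_income", "minority_pct")


@dataclass
class LisaResult:
    """Per-unit local Moran's I, pseudo p-value, and quadrant label."""

    unit_ids: list[str]
    local_I: np.ndarray
    pseudo_p: np.ndarray
    category: list[str]  # HH, HL, LH, LL or ns

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.category:
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_ids,
                "local_I": self.local_I,
                "pseudo_p": self.pseudo_p,
                "category": self.category,
            }
        )


def local_morans(
    graph: ContiguityGraph,
    values: np.ndarray,
    n_permutations: int = 999,
    alpha: float = 0.05,
    rng_seed: int | None = None,
) -> LisaResult:
    """Local Moran's I on row-standardized contiguity weights.

    I_i = z_i * sum_j w_ij z_j with z the standardized value field and
    w_ij = 1/deg(i) for neighbors. Significance comes from conditional
    permutation: z_i is held fixed while its neighbors' values are
    redrawn from the remaining units; the pseudo p-value is the
    one-sided rank of the observed I_i in the permutation distribution.
    Quadrants (HH, HL, LH, LL) are assigned only where pseudo p <= alpha,
    otherwise the unit is "ns". A constant field has no variance and
    yields all-ns with undefined (NaN) I.
    """
    x = np.asarray(values, dtype=float)
    n = graph.n
    if len(x) != n:
        raise ValueError("values must align with graph vertices")
    sd = x.std()
    if sd == 0:
        return LisaResult(
            list(graph.vertices),
            np.full(n, np.nan),
            np.ones(n),
            ["ns"] * n,
        )
    z = (x - x.mean()) / sd

    idx = graph.index()
    nbr_idx = [
        np.array([idx[u] for u in graph.neighbor_map[v]], dtype=int)
        for v in graph.vertices
    ]
    lag = np.array([z[js].mean() if len(js) else 0.0 for js in nbr_idx])
    I_obs = z * lag

    rng = np.random.default_rng(rng_seed)
    pseudo_p = np.ones(n)
    for i in range(n):
        k = len(nbr_idx[i])
        if k == 0:
            continue
        others = np.delete(z, i)
        # conditional permutation: resample neighbor values from the
        # remaining n-1 units
        draws = others[rng.integers(0, n - 1, size=(n_permutations, k))]
        I_perm = z[i] * draws.mean(axis=1)
        if I_obs[i] >= 0:
            extreme = int((I_perm >= I_obs[i]).sum())
        else:
            extreme = int((I_perm <= I_obs[i]).sum())
        pseudo_p[i] = (extreme + 1) / (n_permutations + 1)

    category = []
    for i in range(n):
        if len(nbr_idx[i]) == 0 or pseudo_p[i] > alpha:
            category.append("ns")
        elif z[i] > 0:
            category.append("HH" if lag[i] > 0 else "HL")
        else:
            category.append("LH" if lag[i] > 0 else "LL")
    return LisaResult(list(graph.vertices), I_obs, pseudo_p, category)


def lisa_quadrants(graph: ContiguityGraph, values: np.ndarray) -> list[str]:
    """Quadrant labels without inference (every unit labeled)."""
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0:
        return ["ns"] * graph.n
    z = (x - x.mean()) / sd
    idx = graph.index()
    labels = []
    for v in graph.vertices:
        js = [idx[u] for u in graph.neighbor_map[v]]
        lag = z[js].mean() if js else 0.0
        zi = z[idx[v]]
        if zi > 0:
            labels.append("HH" if lag > 0 else "HL")
        else:
            labels.append("LH" if lag > 0 else "LL")
    return labels


def threshold_convergence(
    runs: Sequence[ThresholdVector | np.ndarray],
    probe_units: Sequence[int],
) -> pd.DataFrame:
    """Cumulative mean of each probe unit's threshold across runs
    1..r — the stability diagnostic for repeated calibrations."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    mat = np.stack(
        [r.values if isinstance(r, ThresholdVector) else np.asarray(r, float) for r in runs]
    )
    out = {}
    r = np.arange(1, len(runs) + 1)
    for u in probe_units:
        out[f"unit_{u}"] = np.cumsum(mat[:, u]) / r
    return pd.DataFrame(out, index=pd.Index(r, name="run"))


def multiplier_set_stability(runs: Sequence[MultiplierSet]) -> np.ndarray:
    """Cumulative mean of the set difference |M_1 \\ M_r| across runs.

    The difference of run r against the run-1 reference is
    N - |members_r ∩ members_1|; the returned series is its running
    mean over the non-reference runs r = 2..R (length R - 1).
    """
    Ns = {r.N for r in runs}
    if len(Ns) != 1:
        raise ValueError("all runs must share N")
    N = Ns.pop()
    ref = runs[0].members
    diffs = np.array([N - len(r.members & ref) for r in runs[1:]], dtype=float)
    return np.cumsum(diffs) / np.arange(1, len(diffs) + 1)


def disparity_summary(
    multipliers: MultiplierSet, demographics: pd.DataFrame
) -> dict[str, dict[str, float | None]]:
    """Median and quartiles of each sociodemographic attribute within
    the multiplier set vs its complement, plus the median difference
    (multiplier minus non-multiplier)."""
    demo = demographics.set_index("unit_id")
    missing = [u for u in multipliers.members if u not in demo.index]
    if missing:
        raise ValueError(f"demographics missing for units: {sorted(missing)[:5]}")
    in_set = demo.index.isin(multipliers.members)
    out: dict[str, dict[str, float | None]] = {}
    for attr in DEMOGRAPHIC_ATTRS:
        grp_m = demo.loc[in_set, attr]
        grp_o = demo.loc[~in_set, attr]
        entry: dict[str, float | None] = {
            "multiplier_median": float(grp_m.median()),
            "multiplier_q1": float(grp_m.quantile(0.25)),
            "multiplier_q3": float(grp_m.quantile(0.75)),
            "n_multiplier": int(in_set.sum()),
            "n_other": int((~in_set).sum()),
        }
        if len(grp_o):
            entry["other_median"] = float(grp_o.median())
            entry["other_q1"] = float(grp_o.quantile(0.25))
            entry["other_q3"] = float(grp_o.quantile(0.75))
            entry["median_difference"] = entry["multiplier_median"] - entry["other_median"]
        else:  # multipliers = all units
            entry["other_median"] = None
            entry["median_difference"] = None
        out[attr] = entry
    return out


def threshold_moments(tau: ThresholdVector | np.ndarray, ddof: int = 0) -> tuple[float, float]:
    """Mean and (population, ddof=0) variance of the threshold field,
    pinned-zero units included."""
    v = tau.values if isinstance(tau, ThresholdVector) else np.asarray(tau, float)
    if len(v) < 1:
        raise ValueError("empty threshold vector")
    return float(v.mean()), float(v.var(ddof=ddof))


def read_demographics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": str})
    for col in DEMOGRAPHIC_ATTRS:
        if col not in df.columns:
            raise ValueError(f"demographics CSV missing column {col!r}")
    if (df[["median_household_income", "per_capita_income"]] < 0).any().any():
        raise ValueError("incomes must be non-negative")
    if ((df["minority_pct"] < 0) | (df["minority_pct"] > 100)).any():
        raise ValueError("minority_pct must lie in [0, 100]")
    return df
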