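"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import box

from recovnet.spatial import ContiguityGraph, SpatialUnit, build_contiguity_graph


def grid_units(rows: int, cols: int) -> list[SpatialUnit]:
    """Unit-square lattice, row-major ids g00, g01, ..."""
    return [
        SpatialUnit(f"g{r}{c}", box(c, r, c + 1, r + 1))
        for r in range(rows)
        for c in range(cols)
    ]


@pytest.fixture
def grid3():
    return grid_units(3, 3)


@pytest.fixture
def queen3(grid3):
    return build_contiguity_graph(grid3, rule="queen")


def path_graph(n: int) -> ContiguityGraph:
    ids = [f"p{i}" for i in range(n)]
    nbrs = {v: set() for v in ids}
    for i in range(n - 1):
        nbrs[ids[i]].add(ids[i + 1])
        nbrs[ids[i + 1]].add(ids[i])
    return ContiguityGraph.from_neighbors(ids, nbrs)


def random_graph(n: int, p: float, rng: np.random.Generator) -> ContiguityGraph:
    """Erdos-Renyi graph (isolates retained) with string vertex ids."""
    ids = [f"r{i}" for i in range(n)]
    nbrs = {v: set() for v in ids}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                nbrs[ids[i]].add(ids[j])
                nbrs[ids[j]].add(ids[i])
    return ContiguityGraph.from_neighbors(ids, nbrs)


def brute_force_diffusion(
    graph: ContiguityGraph,
    tau: dict[str, float],
    seeds: set[str],
    T: int,
    first_update_week: int = 2,
) -> np.ndarray:
    """From-scratch re-evaluation of the threshold update rule each
    week, in pure python over the neighbor map. Independent of the
    vectorized engine it cross-checks."""
    order = graph.vertices
    state = {v: v in seeds for v in order}
    rows = [[state[v] for v in order]]
    for t in range(1, T + 1):
        if t >= first_update_week:
            new = {}
            for v in order:
                ns = graph.neighbor_map[v]
                frac = (
                    sum(state[u] for u in ns) / len(ns) if ns else 0.0
                )
                new[v] = state[v] or frac >= tau[v]
            state = new
        rows.append([state[v] for v in order])
    return np.array(rows, dtype=bool).T  # (n, T+1)
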