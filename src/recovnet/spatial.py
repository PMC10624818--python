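"""Spatial contiguity networks over polygon units.

Builds queen / rook / bishop contiguity graphs from polygon geometries
(the adjacency structure that drives the recovery diffusion model) and
computes the usual undirected-graph summaries: average node degree
k = 2m/n and density d = 2m/(n(n-1)).

Contiguity semantics:

* rook   — two units share a boundary segment of positive length;
* bishop — two units touch only at isolated points (dimension-0 contact);
* queen  — rook or bishop, i.e. any boundary contact at all.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
import shapely
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

__all__ = [
    "SpatialUnit",
    "ContiguityGraph",
    "GraphStats",
    "build_contiguity_graph",
    "graph_from_edgelist",
    "graph_stats",
    "stats_from_counts",
    "read_geojson_units",
    "read_edgelist_csv",
    "write_edgelist_csv",
    "write_stats_json",
]

CONTIGUITY_RULES = ("queen", "rook", "bishop")


@dataclass(frozen=True)
class SpatialUnit:
    """A spatial analysis unit (e.g. a census block group).

    geometry may be None when adjacency is supplied as an edge list.
    """

    unit_id: str
    geometry: BaseGeometry | None = None


@dataclass
class ContiguityGraph:
    """Undirected contiguity graph over spatial units.

    vertices preserve input order; edges are stored as sorted unit-id
    tuples; neighbor_map[v] is the set N(v) of units adjacent to v.
    """

    vertices: list[str]
    edges: set[tuple[str, str]]
    neighbor_map: dict[str, set[str]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate unit_id in vertex list")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on unit {a!r}")

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def m(self) -> int:
        return len(self.edges)

    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.vertices)}

    def degrees(self) -> np.ndarray:
        """Degree per vertex, aligned to vertex order."""
        return np.array([len(self.neighbor_map[v]) for v in self.vertices])

    def adjacency(self) -> sp.csr_matrix:
        """Sparse symmetric 0/1 adjacency matrix in vertex order."""
        idx = self.index()
        rows, cols = [], []
        for a, b in self.edges:
            ia, ib = idx[a], idx[b]
            rows += [ia, ib]
            cols += [ib, ia]
        data = np.ones(len(rows), dtype=np.int8)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_neighbors(
        cls, vertices: Sequence[str], neighbor_map: Mapping[str, Iterable[str]]
    ) -> "ContiguityGraph":
        nbrs = {v: set(neighbor_map.get(v, ())) for v in vertices}
        edges = {tuple(sorted((a, b))) for a, ns in nbrs.items() for b in ns}
        return cls(list(vertices), edges, nbrs)


@dataclass(frozen=True)
class GraphStats:
    """Summary statistics of a contiguity graph."""

    n: int
    m: int
    avg_degree: float
    density: float

    def rounded(self) -> dict[str, float]:
        """Display form: k to 3 decimals, d to 3 significant digits."""
        return {
            "n": self.n,
            "m": self.m,
            "avg_degree": round(self.avg_degree, 3),
            "density": float(f"{self.density:.3g}"),
        }


def _as_parts(geom: BaseGeometry) -> list[BaseGeometry]:
    if geom.geom_type in ("MultiPolygon", "GeometryCollection"):
        return [g for g in geom.geoms if g.geom_type in ("Polygon", "MultiPolygon")]
    return [geom]


def _prepare_geometry(unit: SpatialUnit, snap_tolerance: float) -> BaseGeometry:
    geom = unit.geometry
    if geom is None:
        raise ValueError(
            f"unit {unit.unit_id!r} has no geometry; edge list required"
        )
    if not geom.is_valid:
        geom = make_valid(geom)
        if not geom.is_valid:
            raise ValueError(f"invalid geometry for unit {unit.unit_id!r}")
    if snap_tolerance and snap_tolerance > 0:
        geom = shapely.set_precision(geom, snap_tolerance)
    return geom


def build_contiguity_graph(
    units: Sequence[SpatialUnit],
    rule: str = "queen",
    snap_tolerance: float = 0.0,
) -> ContiguityGraph:
    """Build a contiguity graph from polygon units.

    Parameters
    ----------
    units
        Spatial units with polygon/multipolygon geometries in one
        planar coordinate system. Input order is preserved as vertex
        order. Multipolygon units are neighbors if any part touches.
    rule
        "queen" (edge or vertex contact), "rook" (edge contact) or
        "bishop" (vertex-only contact).
    snap_tolerance
        Coordinate snapping grid applied before contact detection;
        0 means exact coordinates. Use a small positive value for
        shapefiles whose shared boundaries are not digitized
        identically.
    """
    if rule not in CONTIGUITY_RULES:
        raise ValueError(f"rule must be one of {CONTIGUITY_RULES}, got {rule!r}")
    if len(units) < 2:
        raise ValueError("need at least 2 units to build a contiguity graph")
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate unit_id among units")

    geoms = [_prepare_geometry(u, snap_tolerance) for u in units]
    tree = shapely.STRtree(geoms)
    nbrs: dict[str, set[str]] = {v: set() for v in ids}

    # STRtree returns bbox-overlap candidates; classify each pair once by
    # the dimension of the geometric intersection.
    left, right = tree.query(np.array(geoms, dtype=object), predicate="intersects")
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j:
            continue
        inter = geoms[i].intersection(geoms[j])
        if inter.is_empty:
            continue
        # positive-length (or areal, for overlapping inputs) contact -> rook
        rook_contact = inter.length > 0 or inter.area > 0
        if rule == "rook" and not rook_contact:
            continue
        if rule == "bishop" and rook_contact:
            continue
        nbrs[ids[i]].add(ids[j])
        nbrs[ids[j]].add(ids[i])

    return ContiguityGraph.from_neighbors(ids, nbrs)


def graph_from_edgelist(edges: Iterable[tuple[str, str]]) -> ContiguityGraph:
    """Build a contiguity graph from unit-id pairs.

    Duplicate and reversed pairs collapse to a single undirected edge;
    self-loops are rejected. Vertex order is first appearance.
    """
    vertices: list[str] = []
    seen: set[str] = set()
    edge_set: set[tuple[str, str]] = set()
    for a, b in edges:
        a, b = str(a), str(b)
        if a == b:
            raise ValueError(f"self-loop on unit {a!r}")
        for v in (a, b):
            if v not in seen:
                seen.add(v)
                vertices.append(v)
        edge_set.add(tuple(sorted((a, b))))
    nbrs: dict[str, set[str]] = {v: set() for v in vertices}
    for a, b in edge_set:
        nbrs[a].add(b)
        nbrs[b].add(a)
    return ContiguityGraph(vertices, edge_set, nbrs)


def graph_stats(g: ContiguityGraph) -> GraphStats:
    """Average degree k = 2m/n and density d = 2m/(n(n-1))."""
    if g.n < 2:
        raise ValueError("density undefined for n < 2")
    return stats_from_counts(g.n, g.m)


def stats_from_counts(n: int, m: int) -> GraphStats:
    """Graph summaries from vertex and edge counts alone."""
    if n < 2:
        raise ValueError("density undefined for n < 2")
    k = 2.0 * m / n
    d = 2.0 * m / (n * (n - 1))
    return GraphStats(n=n, m=m, avg_degree=k, density=d)


# ---------------------------------------------------------------------------
# IO


def read_geojson_units(path: str | Path, id_property: str = "unit_id") -> list[SpatialUnit]:
    """Read polygon features from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    units = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        uid = str(props.get(id_property, k))
        units.append(SpatialUnit(uid, _shapely_shape(feat["geometry"])))
    return units


def read_edgelist_csv(path: str | Path) -> ContiguityGraph:
    df = pd.read_csv(path, dtype=str)
    return graph_from_edgelist(list(zip(df["src"], df["dst"])))


def write_edgelist_csv(g: ContiguityGraph, path: str | Path) -> None:
    rows = sorted(g.edges)
    pd.DataFrame(rows, columns=["src", "dst"]).to_csv(path, index=False)


def write_stats_json(stats: GraphStats, path: str | Path) -> None:
    payload = {
        "n": stats.n,
        "m": stats.m,
        "avg_degree": stats.avg_degree,
        "density": stats.density,
        "display": stats.rounded(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
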