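"""Epsilon-regular graphs: a quantitative time-series-to-network transform.

Every sample of a time series becomes a vertex; two vertices are adjacent
iff their sample values differ by at most ``epsilon`` (inclusive).  Because
adjacency depends only on values, the graph is an interval graph on the
real line: after sorting the values, each vertex's neighbourhood is a
contiguous run, and connected components are maximal runs whose consecutive
sorted gaps do not exceed ``epsilon``.  Degrees, edge counts and components
are therefore computed from the sorted order in O(n log n) without ever
materializing the edge set, which for dense epsilon would be quadratic.

Value comparisons use exact IEEE arithmetic on the stored samples — the
edge predicate is literally ``abs(values[i] - values[j]) <= epsilon`` with
no tolerance; users who want fuzzier ties should pre-round their data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "TimeSeries",
    "EpsilonGraph",
    "DegreeVector",
    "build_epsilon_graph",
    "degree_centrality",
    "connected_components",
    "is_complete_subgraph",
    "mean_degree",
    "write_edge_list",
    "to_networkx",
]


@dataclass(frozen=True)
class TimeSeries:
    """An ordered sequence of real-valued samples.

    Parameters
    ----------
    values:
        The samples, in time order.  Must be non-empty and finite.
    units_label:
        Free-text unit annotation, e.g. ``"s"`` for R-R intervals in
        seconds.  Purely descriptive.
    """

    values: np.ndarray
    units_label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("a time series must be one-dimensional")
        if arr.size < 1:
            raise ValueError("a time series must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValueError("time series samples must be finite (no NaN/Inf)")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size


def as_series(series: "TimeSeries | Sequence[float] | np.ndarray", units_label: str = "") -> TimeSeries:
    """Coerce an array-like into a :class:`TimeSeries` (validating it)."""
    if isinstance(series, TimeSeries):
        return series
    return TimeSeries(np.asarray(series, dtype=float), units_label)


def _neighbor_ranges(sorted_vals: np.ndarray, eps: float) -> tuple[np.ndarray, np.ndarray]:
    """Half-open index range [lo, hi) of sorted values within eps of each sorted value.

    ``searchsorted`` against ``v ± eps`` can be off by a few positions when
    ``v ± eps`` rounds across a data value (the defining predicate is
    ``abs(a - b) <= eps``, not ``b <= fl(v + eps)``); the rare disagreements
    are repaired by a local scan so the result is extensionally exact.
    """
    n = sorted_vals.size
    lo = np.searchsorted(sorted_vals, sorted_vals - eps, side="left")
    hi = np.searchsorted(sorted_vals, sorted_vals + eps, side="right")

    idx = np.arange(n)
    bad_lo = ((lo > 0) & (np.abs(sorted_vals[np.maximum(lo - 1, 0)] - sorted_vals) <= eps)) | (
        (lo < idx) & (np.abs(sorted_vals[np.minimum(lo, n - 1)] - sorted_vals) > eps)
    )
    bad_hi = ((hi < n) & (np.abs(sorted_vals[np.minimum(hi, n - 1)] - sorted_vals) <= eps)) | (
        (hi > idx + 1) & (np.abs(sorted_vals[np.maximum(hi - 1, 0)] - sorted_vals) > eps)
    )
    for i in np.nonzero(bad_lo)[0]:
        v, l = sorted_vals[i], int(lo[i])
        while l > 0 and abs(v - sorted_vals[l - 1]) <= eps:
            l -= 1
        while l < i and abs(v - sorted_vals[l]) > eps:
            l += 1
        lo[i] = l
    for i in np.nonzero(bad_hi)[0]:
        v, h = sorted_vals[i], int(hi[i])
        while h < n and abs(sorted_vals[h] - v) <= eps:
            h += 1
        while h > i + 1 and abs(sorted_vals[h - 1] - v) > eps:
            h -= 1
        hi[i] = h
    return lo, hi


@dataclass
class EpsilonGraph:
    """Simple undirected graph on the indices of a time series.

    Vertex ``i`` corresponds to sample ``i``; the edge ``(i, j)`` exists
    iff ``abs(values[i] - values[j]) <= epsilon``.  The graph keeps the
    sample values and answers degree/component/completeness queries from
    the sorted order; the explicit edge set is only built on demand
    (:meth:`iter_edges`), since it can be quadratic in size.
    """

    values: np.ndarray
    epsilon: float
    _order: np.ndarray = field(init=False, repr=False)
    _sorted: np.ndarray = field(init=False, repr=False)
    _lo: np.ndarray = field(init=False, repr=False)
    _hi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._order = np.argsort(self.values, kind="stable")
        self._sorted = self.values[self._order]
        self._lo, self._hi = _neighbor_ranges(self._sorted, self.epsilon)

    @property
    def n_vertices(self) -> int:
        return self.values.size

    @property
    def n_edges(self) -> int:
        # each degree counts the vertex's sorted-window size minus itself
        return int((self._hi - self._lo - 1).sum()) // 2

    def degrees(self) -> np.ndarray:
        """Raw degree of every vertex, aligned to original indices."""
        deg_sorted = self._hi - self._lo - 1
        out = np.empty(self.n_vertices, dtype=np.int64)
        out[self._order] = deg_sorted
        return out

    def mean_degree(self) -> float:
        """Average vertex degree, ``2|E| / n``."""
        return float((self._hi - self._lo - 1).mean())

    def iter_edges(self) -> Iterator[tuple[int, int]]:
        """Yield edges as (i, j) pairs with i < j, in lexicographic order.

        Materializes the edge list lazily; for near-complete graphs this is
        O(n^2) and intended for export or small graphs.
        """
        n = self.n_vertices
        rank = np.empty(n, dtype=np.int64)
        rank[self._order] = np.arange(n)
        edges = []
        for i in range(n):
            r = rank[i]
            for s in range(self._lo[r], self._hi[r]):
                j = int(self._order[s])
                if j > i:
                    edges.append((i, j))
        edges.sort()
        yield from edges

    def connected_components(self) -> list[list[int]]:
        """Partition of vertex indices into connected components.

        Components are contiguous runs in value-sorted order separated by
        gaps larger than epsilon.  Ordered by smallest member index;
        members ascending.
        """
        n = self.n_vertices
        gaps = np.diff(self._sorted)
        # break after sorted position k when the consecutive gap exceeds eps
        breaks = np.nonzero(gaps > self.epsilon)[0]
        comps = []
        start = 0
        for b in list(breaks) + [n - 1]:
            members = sorted(int(v) for v in self._order[start : b + 1])
            comps.append(members)
            start = b + 1
        comps.sort(key=lambda c: c[0])
        return comps

    def is_complete_subgraph(self, vertex_subset: Iterable[int]) -> bool:
        """True iff every pair of the given vertices is an edge.

        Pairwise closeness of a set is equivalent to its value range not
        exceeding epsilon.  Singletons and the empty set are vacuously
        complete.
        """
        idx = np.asarray(list(vertex_subset), dtype=np.int64)
        if idx.size == 0:
            return True
        if idx.min() < 0 or idx.max() >= self.n_vertices:
            raise IndexError("vertex index out of range")
        vals = self.values[idx]
        return bool(abs(vals.max() - vals.min()) <= self.epsilon)


@dataclass(frozen=True)
class DegreeVector:
    """Per-vertex degree centrality, raw or normalized by n-1."""

    degrees: np.ndarray
    normalized: bool


def build_epsilon_graph(series, epsilon: float) -> EpsilonGraph:
    """Build the epsilon-regular graph of a time series.

    Parameters
    ----------
    series:
        A :class:`TimeSeries` or array-like of finite samples.
    epsilon:
        Adjacency threshold, same units as the samples; must be a finite
        non-negative real.  Two samples are joined iff their absolute
        difference is at most ``epsilon`` (boundary ties are edges).
    """
    ts = as_series(series)
    eps = float(epsilon)
    if not np.isfinite(eps) or eps < 0:
        raise ValueError(f"epsilon must be finite and >= 0, got {epsilon!r}")
    return EpsilonGraph(ts.values, eps)


def degree_centrality(graph: EpsilonGraph, normalized: bool = False) -> DegreeVector:
    """Degree centrality of every vertex.

    Raw degrees count neighbors; normalized degrees divide by ``n - 1``,
    mapping onto the unit interval.
    """
    deg = graph.degrees()
    if normalized:
        if graph.n_vertices < 2:
            raise ValueError("normalized degree is undefined for a single-vertex graph")
        return DegreeVector(deg / (graph.n_vertices - 1), True)
    return DegreeVector(deg, False)


def connected_components(graph: EpsilonGraph) -> list[list[int]]:
    return graph.connected_components()


def is_complete_subgraph(graph: EpsilonGraph, vertex_subset: Iterable[int]) -> bool:
    return graph.is_complete_subgraph(vertex_subset)


def mean_degree(graph: EpsilonGraph) -> float:
    return graph.mean_degree()


def write_edge_list(graph, path) -> None:
    """Write the edge list as two 0-based integer columns.

    A header comment records n and, for epsilon graphs, epsilon.  Works for
    any object exposing ``n_vertices`` and ``iter_edges``.
    """
    eps = getattr(graph, "epsilon", None)
    with open(path, "w") as fh:
        if eps is not None:
            fh.write(f"# epsilon={eps!r} n={graph.n_vertices}\n")
        else:
            fh.write(f"# n={graph.n_vertices}\n")
        for i, j in graph.iter_edges():
            fh.write(f"{i}\t{j}\n")


def to_networkx(graph):
    """Convert to a :class:`networkx.Graph` (e.g. for GraphML export)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(graph.n_vertices))
    values = getattr(graph, "values", None)
    if values is not None:
        nx.set_node_attributes(g, {i: float(v) for i, v in enumerate(values)}, "value")
    g.add_edges_from(graph.iter_edges())
    eps = getattr(graph, "epsilon", None)
    if eps is not None:
        g.graph["epsilon"] = float(eps)
    return g
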