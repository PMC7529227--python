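"""Natural visibility graphs, the qualitative comparator transform.

Samples sit at integer times t_i = i; two samples (a, y_a) and (b, y_b)
are adjacent iff the straight segment between them passes strictly above
every intermediate sample — equivalently, iff the slope from a to b
strictly exceeds the slope from a to every c in between.  Equality blocks
visibility (a collinear intermediate point obstructs).

The construction sweeps rightward from each vertex keeping the running
maximum slope, which is O(n^2) overall against the naive O(n^3)
all-intermediates check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .core import as_series

__all__ = ["VisibilityGraph", "build_visibility_graph"]


@dataclass
class VisibilityGraph:
    """Simple undirected visibility graph on series indices.

    Always contains the path 0-1-...-(n-1) (consecutive samples see each
    other), hence is connected.
    """

    n_vertices: int
    edges: frozenset[tuple[int, int]]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def iter_edges(self) -> Iterator[tuple[int, int]]:
        yield from sorted(self.edges)


def build_visibility_graph(series) -> VisibilityGraph:
    """Build the natural visibility graph of a time series.

    Uses the strict-inequality convention: an intermediate point lying
    exactly on the sight line blocks the edge.  Time stamps are the sample
    indices (uniform spacing).
    """
    ts = as_series(series)
    y = ts.values
    n = y.size
    if n < 2:
        raise ValueError("visibility graph requires at least 2 samples")
    edges: set[tuple[int, int]] = set()
    for a in range(n - 1):
        edges.add((a, a + 1))
        max_slope = (y[a + 1] - y[a])  # slope to the immediate neighbour
        for b in range(a + 2, n):
            s = (y[b] - y[a]) / (b - a)
            if s > max_slope:
                edges.add((a, b))
                max_slope = s
    return VisibilityGraph(n, frozenset(edges))
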