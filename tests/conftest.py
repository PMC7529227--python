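import numpy as np
import pytest

# The 10-point demonstration series: three repeated levels (0.2, 0.29,
# 0.38 within reach of each other at eps=0.1) plus three 0.7 outliers.
DEMO_SERIES = [0.2, 0.29, 0.7, 0.29, 0.38, 0.7, 0.2, 0.38, 0.7, 0.2]
DEMO_EPS = 0.1


@pytest.fixture
def demo_series():
    return list(DEMO_SERIES)


def brute_epsilon_edges(values, eps):
    """O(n^2) all-pairs reference edge set for the epsilon-regular graph."""
    values = np.asarray(values, dtype=float)
    n = values.size
    return {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(values[i] - values[j]) <= eps
    }


def brute_visibility_edges(values):
    """O(n^3) all-intermediates reference edge set for the visibility graph."""
    y = np.asarray(values, dtype=float)
    n = y.size
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            visible = all(
                y[c] < y[b] + (y[a] - y[b]) * (b - c) / (b - a)
                for c in range(a + 1, b)
            )
            if visible:
                edges.add((a, b))
    return edges
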