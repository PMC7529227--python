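"""Epsilon-regular graph construction and graph-theoretic summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epsigraph import (
    build_epsilon_graph,
    connected_components,
    degree_centrality,
    is_complete_subgraph,
    mean_degree,
    to_networkx,
    write_edge_list,
)
from conftest import DEMO_EPS, brute_epsilon_edges

finite_values = st.floats(
    min_value=-1e9, max_value=1e9, allow_nan=False, allow_infinity=False
)
series_strategy = st.lists(finite_values, min_size=1, max_size=60)
eps_strategy = st.floats(min_value=0, max_value=1e9, allow_nan=False)


class TestWorkedExample:
    """The 10-point three-level demonstration series at eps=0.1."""

    def test_edge_count_and_mean_degree(self, demo_series):
        g = build_epsilon_graph(demo_series, DEMO_EPS)
        assert g.n_edges == 18
        assert mean_degree(g) == pytest.approx(3.6)
        assert set(g.iter_edges()) == brute_epsilon_edges(demo_series, DEMO_EPS)

    def test_degrees(self, demo_series):
        g = build_epsilon_graph(demo_series, DEMO_EPS)
        assert degree_centrality(g).degrees.tolist() == [4, 6, 2, 6, 3, 2, 4, 3, 2, 4]

    def test_outliers_form_their_own_component(self, demo_series):
        comps = connected_components(build_epsilon_graph(demo_series, DEMO_EPS))
        assert sorted(map(len, comps)) == [3, 7]
        assert [2, 5, 8] in comps  # the three 0.7-valued outliers

    def test_moderate_outlier_stays_connected(self, demo_series):
        softened = [0.48 if v == 0.7 else v for v in demo_series]
        comps = connected_components(build_epsilon_graph(softened, DEMO_EPS))
        assert len(comps) == 1

    def test_complete_subgraphs(self, demo_series):
        g = build_epsilon_graph(demo_series, DEMO_EPS)
        assert is_complete_subgraph(g, [0, 6, 9])  # the three 0.2 values: K3
        assert is_complete_subgraph(g, [2, 5, 8])  # the periodic 0.7 values
        assert not is_complete_subgraph(g, [0, 4])  # |0.2 - 0.38| > 0.1


class TestDegenerateGraphs:
    def test_zero_epsilon_distinct_values_gives_no_edges(self):
        g = build_epsilon_graph([1.0, 2.0, 3.5, -1.0], 0.0)
        assert g.n_edges == 0
        assert len(connected_components(g)) == 4
        assert degree_centrality(g).degrees.tolist() == [0, 0, 0, 0]

    def test_epsilon_covering_range_gives_complete_graph(self):
        vals = [3.0, -1.0, 0.5, 2.0, 2.0]
        g = build_epsilon_graph(vals, 4.0)
        n = len(vals)
        assert g.n_edges == n * (n - 1) // 2
        assert mean_degree(g) == n - 1
        assert np.allclose(degree_centrality(g, normalized=True).degrees, 1.0)
        assert len(connected_components(g)) == 1

    def test_single_vertex(self):
        g = build_epsilon_graph([0.7], 0.1)
        assert g.n_edges == 0
        assert is_complete_subgraph(g, [0])  # vacuously complete
        with pytest.raises(ValueError):
            degree_centrality(g, normalized=True)

    @pytest.mark.parametrize(
        "values, epsilon",
        [([1.0, np.nan], 0.1), ([1.0, np.inf], 0.1), ([1.0, 2.0], -0.5), ([], 0.1)],
    )
    def test_input_validation(self, values, epsilon):
        with pytest.raises(ValueError):
            build_epsilon_graph(values, epsilon)

    def test_out_of_range_subset_rejected(self, demo_series):
        g = build_epsilon_graph(demo_series, DEMO_EPS)
        with pytest.raises(IndexError):
            is_complete_subgraph(g, [0, 10])


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(series_strategy, eps_strategy)
    def test_matches_brute_force_oracle(self, values, eps):
        g = build_epsilon_graph(values, eps)
        expected = brute_epsilon_edges(values, eps)
        assert set(g.iter_edges()) == expected
        assert g.n_edges == len(expected)
        # degrees and components agree with a networkx view of the edges
        deg = degree_centrality(g).degrees
        assert deg.sum() == 2 * g.n_edges

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(series_strategy, eps_strategy, eps_strategy)
    def test_monotone_in_epsilon(self, values, e1, e2):
        lo, hi = sorted([e1, e2])
        assert set(build_epsilon_graph(values, lo).iter_edges()) <= set(
            build_epsilon_graph(values, hi).iter_edges()
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(series_strategy, eps_strategy)
    def test_equal_values_form_complete_subgraph(self, values, eps):
        g = build_epsilon_graph(values, eps)
        arr = np.asarray(values)
        for v in np.unique(arr):
            assert g.is_complete_subgraph(np.nonzero(arr == v)[0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(series_strategy, eps_strategy, st.randoms(use_true_random=False))
    def test_degree_multiset_is_permutation_invariant(self, values, eps, rnd):
        shuffled = list(values)
        rnd.shuffle(shuffled)
        d1 = sorted(degree_centrality(build_epsilon_graph(values, eps)).degrees)
        d2 = sorted(degree_centrality(build_epsilon_graph(shuffled, eps)).degrees)
        assert d1 == d2

    def test_components_agree_with_networkx(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            vals = rng.normal(size=rng.integers(2, 80))
            eps = float(rng.uniform(0, 2))
            g = build_epsilon_graph(vals, eps)
            import networkx as nx

            nxg = to_networkx(g)
            expected = sorted(
                (sorted(c) for c in nx.connected_components(nxg)), key=lambda c: c[0]
            )
            assert connected_components(g) == expected


class TestExport:
    def test_edge_list_header_and_rows(self, demo_series, tmp_path):
        g = build_epsilon_graph(demo_series, DEMO_EPS)
        path = tmp_path / "edges.tsv"
        write_edge_list(g, path)
        lines = path.read_text().strip().splitlines()
        assert lines[0].startswith("#") and "epsilon=" in lines[0] and "n=10" in lines[0]
        parsed = {tuple(map(int, ln.split())) for ln in lines[1:]}
        assert parsed == set(g.iter_edges())

    def test_networkx_roundtrip(self, demo_series):
        g = build_epsilon_graph(demo_series, DEMO_EPS)
        nxg = to_networkx(g)
        assert nxg.number_of_edges() == 18
        assert nxg.graph["epsilon"] == DEMO_EPS
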