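"""Build an epsilon-regular graph from a small series and inspect it.

The series has three repeated levels (0.2, 0.29, 0.38) that are mutually
within eps = 0.1, and three 0.7-valued outliers that are not: the outliers
end up in their own connected component, and every set of equal values
forms a complete subgraph.
"""

import epsigraph as eg

series = [0.2, 0.29, 0.7, 0.29, 0.38, 0.7, 0.2, 0.38, 0.7, 0.2]
g = eg.build_epsilon_graph(series, epsilon=0.1)

print(f"vertices: {g.n_vertices}, edges: {g.n_edges}, mean degree: {eg.mean_degree(g)}")
print(f"raw degrees:        {eg.degree_centrality(g).degrees.tolist()}")
print(f"normalized degrees: {eg.degree_centrality(g, normalized=True).degrees.round(3).tolist()}")
print(f"components: {eg.connected_components(g)}")
print(f"the three 0.7 points form a complete subgraph: {eg.is_complete_subgraph(g, [2, 5, 8])}")
print(f"the three 0.2 points form K3:                  {eg.is_complete_subgraph(g, [0, 6, 9])}")

# The two components split the 0.7 outliers (indices 2, 5, 8) from the
# rest: an outlier whose value differs by more than eps from everything
# else is structurally isolated, unlike in a visibility graph where an
# extreme point becomes a hub.
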