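"""Contrast the epsilon-regular graph with the natural visibility graph.

Both transforms are applied to the same 10-point series.  In the
epsilon-regular graph the high-valued outliers sit in a separate
component with the minimum degree; in the visibility graph the same
points see over their neighbours and become the best-connected hubs —
the two transforms encode opposite things about extreme values.
"""

import numpy as np

import epsigraph as eg

series = [0.2, 0.29, 0.7, 0.29, 0.38, 0.7, 0.2, 0.38, 0.7, 0.2]
peaks = [i for i, v in enumerate(series) if v == 0.7]

ge = eg.build_epsilon_graph(series, epsilon=0.1)
gv = eg.build_visibility_graph(series)

de = eg.degree_centrality(ge).degrees
dv = gv.degrees()
print(f"epsilon graph:    {ge.n_edges} edges, degrees {de.tolist()}")
print(f"visibility graph: {gv.n_edges} edges, degrees {dv.tolist()}")
print(f"mean degree of the 0.7 peaks: epsilon {de[peaks].mean():.2f} "
      f"(graph mean {de.mean():.2f}), visibility {dv[peaks].mean():.2f} "
      f"(graph mean {dv.mean():.2f})")

# Affine changes of the values leave the visibility graph untouched but
# change the epsilon graph (its threshold is absolute):
scaled = (10 * np.asarray(series) + 3).tolist()
same = set(gv.iter_edges()) == set(eg.build_visibility_graph(scaled).iter_edges())
print(f"visibility edges invariant under y -> 10y + 3: {same}")
print(f"epsilon edges at eps=0.1 after scaling: {eg.build_epsilon_graph(scaled, 0.1).n_edges} (were {ge.n_edges})")
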