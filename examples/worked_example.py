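"""Visibility graph and maxclique graph of a tiny 7-point series.

Builds the graphs for the small example series used throughout the
documentation and prints the graph parameters that later serve as
classification features.
"""

import numpy as np

from visimax import TimeSeries, graph_parameters, maxclique_graph, visibility_graph

series = TimeSeries(
    t=np.arange(7.0),
    y=np.array([1.0, 1.3, 1.7, 2.2, 1.5, 1.7, 0.8]),
)

g = visibility_graph(series)
kg, cliques = maxclique_graph(g)

print("visibility graph edges:", sorted(g.edges()))
print("maxcliques:", cliques)
print("K(G) edges:", sorted(kg.edges()))

p = graph_parameters(g, cliques=cliques)
print(f"G:    order={p.order}  max_degree={p.max_degree}  "
      f"clique_number={p.clique_number}  n_maxcliques={p.n_maxcliques}")
pk = graph_parameters(kg)
print(f"K(G): order={pk.order}  max_degree={pk.max_degree}  "
      f"clique_number={pk.clique_number}  n_maxcliques={pk.n_maxcliques}")

# max_degree is the best-connected sample's neighbour count; clique_number
# the largest set of mutually visible samples; n_maxcliques counts the
# distinct maximal such sets -- the three quantities the classifier uses.
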