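"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: visibility is
checked with the direct triple loop over the line condition, and maximal
cliques by exhaustive subset enumeration.
"""

import networkx as nx
import numpy as np
import pytest

from visimax import TimeSeries

# the published 7-point worked-example series
EQ2_POINTS = [(0, 1.0), (1, 1.3), (2, 1.7), (3, 2.2), (4, 1.5), (5, 1.7), (6, 0.8)]


@pytest.fixture
def worked_series() -> TimeSeries:
    t, y = zip(*EQ2_POINTS)
    return TimeSeries(np.array(t, float), np.array(y, float))


def brute_force_visibility(series: TimeSeries) -> nx.Graph:
    """Direct check of the visibility condition over all pairs and all
    intermediates; O(n^3), the reference any fast construction must match."""
    t, y = series.t, series.y
    n = len(series)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            visible = True
            for c in range(a + 1, b):
                if y[c] >= y[b] + (y[a] - y[b]) * (t[b] - t[c]) / (t[b] - t[a]):
                    visible = False
                    break
            if visible:
                g.add_edge(a, b)
    return g


def brute_force_maxcliques(g: nx.Graph) -> set[frozenset]:
    """All maximal cliques by exhaustive subset enumeration (<= ~15 nodes)."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    adj = {v: set(g.neighbors(v)) for v in nodes}
    cliques = set()
    for mask in range(1, 1 << n):
        subset = [nodes[i] for i in range(n) if mask >> i & 1]
        if all(u in adj[v] for i, v in enumerate(subset) for u in subset[i + 1 :]):
            if not any(
                all(v in adj[w] for v in subset) for w in nodes if w not in subset
            ):
                cliques.add(frozenset(subset))
    # isolated vertices: singleton subsets are handled above; empty graph -> empty
    return cliques
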