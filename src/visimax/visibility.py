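"""Natural visibility graphs of time series.

Each sample of a series becomes a vertex (vertex i is the i-th sample in
temporal order).  Two samples (t_a, y_a) and (t_b, y_b) with t_a < t_b are
connected exactly when every intermediate sample (t_c, y_c), t_a < t_c < t_b,
lies strictly below the straight line joining them:

    y_c < y_b + (y_a - y_b) * (t_b - t_c) / (t_b - t_a).

The inequality is strict: an intermediate point exactly on the sight line
blocks visibility.  Comparisons use exact floating-point arithmetic with no
epsilon, so users with noisy, near-collinear data may want to jitter their
amplitudes first.  Consecutive samples have no intermediate point and are
always adjacent, so the graph always contains the temporal Hamiltonian path
0-1-...-(n-1) and is connected.

The construction scans, for each left endpoint a, the running maximum of
the slope (y_c - y_a)/(t_c - t_a) over samples after a; b is visible from a
iff the slope to b strictly exceeds that maximum, which is algebraically
identical to the line condition above.
"""

from __future__ import annotations

import math

import networkx as nx

from .signal_io import TimeSeries


def visibility_graph(series: TimeSeries) -> nx.Graph:
    """Build the natural visibility graph of ``series``.

    Parameters
    ----------
    series : TimeSeries
        At least two samples; finiteness and strictly increasing t are
        enforced by the type.

    Returns
    -------
    networkx.Graph
        Simple undirected graph on vertices 0..n-1.
    """
    n = len(series)
    if n < 2:
        raise ValueError("visibility graph needs at least 2 samples")
    t = series.t
    y = series.y
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n - 1):
        ta = t[a]
        ya = y[a]
        max_slope = -math.inf
        for b in range(a + 1, n):
            slope = (y[b] - ya) / (t[b] - ta)
            if slope > max_slope:
                g.add_edge(a, b)
                max_slope = slope
            # an intermediate on or above the sight line keeps blocking
    return g


def graph_summary(g: nx.Graph) -> dict:
    """JSON-ready summary {n_vertices, n_edges}."""
    return {"n_vertices": g.number_of_nodes(), "n_edges": g.number_of_edges()}


def write_edge_list(g: nx.Graph, path) -> None:
    """Write a two-column edge list with 0-based vertex ids."""
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{u} {v}\n")
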