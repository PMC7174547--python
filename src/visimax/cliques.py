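"""Maxclique enumeration, the maxclique-graph operator K(G), and the
graph parameters used as waveform features.

A *maxclique* of a graph G is a maximal clique: a set of pairwise-adjacent
vertices that no outside vertex extends.  The *maxclique graph* K(G) has
one vertex per maxclique of G, two of them adjacent whenever the cliques
share at least one vertex of G.  |K(G)| — the number of maxcliques — is
therefore the order of K(G).

Cliques are reported in a canonical order (each clique sorted ascending,
cliques sorted lexicographically, i.e. by minimum vertex first) so that
K(G) vertex ids, exports and tests are reproducible.

Enumeration is delegated to Bron-Kerbosch with pivoting
(:func:`networkx.find_cliques`).  The number of maximal cliques can be
exponential in the worst case, so enumeration aborts with
:class:`CliqueCeilingError` past a configurable ceiling; the visibility
graphs this package builds are sparse and stay far below it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import networkx as nx

DEFAULT_CLIQUE_CEILING = 10**6

Clique = tuple[int, ...]


class CliqueCeilingError(RuntimeError):
    """The graph has more maximal cliques than the configured ceiling."""


@dataclass(frozen=True)
class GraphParameters:
    """The scalar graph descriptors used as features.

    Attributes
    ----------
    order : int
        |G|, the number of vertices.
    max_degree : int
        Delta(G), the largest vertex degree.
    clique_number : int
        omega(G), the size of the largest maxclique.
    n_maxcliques : int
        |K(G)|, the number of maxcliques.
    """

    order: int
    max_degree: int
    clique_number: int
    n_maxcliques: int

    def as_dict(self) -> dict:
        return asdict(self)


def enumerate_maxcliques(
    g: nx.Graph, ceiling: int = DEFAULT_CLIQUE_CEILING
) -> list[Clique]:
    """Enumerate all maximal cliques of ``g`` in canonical order.

    Returns an empty list for the empty graph. Isolated vertices form
    singleton maxcliques, so every vertex appears in at least one member.
    """
    cliques: list[Clique] = []
    for c in nx.find_cliques(g):
        cliques.append(tuple(sorted(c)))
        if len(cliques) > ceiling:
            raise CliqueCeilingError(
                f"more than {ceiling} maximal cliques; raise `ceiling` to "
                "proceed (clique counts grow exponentially in the worst case)"
            )
    cliques.sort()
    return cliques


def maxclique_graph(
    g: nx.Graph, ceiling: int = DEFAULT_CLIQUE_CEILING
) -> tuple[nx.Graph, list[Clique]]:
    """Apply the maxclique-graph operator.

    Vertex i of the result is the i-th maxclique of ``g`` in canonical
    order; {i, j} is an edge iff the two cliques intersect.  The clique
    list is returned alongside for traceability.
    """
    cliques = enumerate_maxcliques(g, ceiling=ceiling)
    kg = nx.Graph()
    kg.add_nodes_from(range(len(cliques)))
    members = [frozenset(c) for c in cliques]
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if not members[i].isdisjoint(members[j]):
                kg.add_edge(i, j)
    return kg, cliques


def graph_parameters(
    g: nx.Graph, cliques: list[Clique] | None = None
) -> GraphParameters:
    """Compute order, Delta(G), omega(G) and |K(G)| for a non-empty graph.

    ``cliques`` may be passed to reuse an existing enumeration; it must be
    the maxclique set of ``g``.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph parameters are undefined for the empty graph")
    if cliques is None:
        cliques = enumerate_maxcliques(g)
    return GraphParameters(
        order=g.number_of_nodes(),
        max_degree=max(d for _, d in g.degree),
        clique_number=max(len(c) for c in cliques),
        n_maxcliques=len(cliques),
    )


def write_cliques(cliques: list[Clique], path) -> None:
    """Write one clique per line, space-separated vertex ids."""
    with open(path, "w") as fh:
        for c in cliques:
            fh.write(" ".join(str(v) for v in c) + "\n")
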