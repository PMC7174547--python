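"""Per-burst graph-parameter features and unsupervised sigh / non-sigh
classification.

Each burst is decimated, turned into its visibility graph G, and the
maxclique-graph operator applied to give K(G).  Six integer features are
recorded per burst: the maximum degree, clique number and number of
maxcliques of both G and K(G) (the number of maxcliques of K(G) applies
the operator twice, i.e. it is |K(K(G))|).

Classification is K-means with k = 2 on a chosen pair of features.
Physiologically, a sigh is a large biphasic burst with many small
fluctuations; its visibility graph therefore fragments into many small
cliques and the number-of-maxcliques features are large.  The cluster
whose centroid has the larger number-of-maxcliques coordinate is labelled
"sigh"; if neither chosen feature is a maxclique count, the cluster with
the larger centroid norm (raw feature space) is.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .cliques import graph_parameters, maxclique_graph
from .signal_io import BurstSegment, downsample
from .visibility import visibility_graph

logger = logging.getLogger(__name__)

SIGH = "sigh"
NON_SIGH = "non-sigh"

FEATURE_FIELDS = (
    "g_max_degree",
    "g_clique_number",
    "g_n_maxcliques",
    "kg_max_degree",
    "kg_clique_number",
    "kg_n_maxcliques",
)

#: feature pair the classifier defaults to: clique number and number of
#: maxcliques of the maxclique graph, the best-separating combination.
DEFAULT_FEATURE_PAIR = ("kg_clique_number", "kg_n_maxcliques")


class DegenerateFeatureError(ValueError):
    """All feature points coincide; K-means with k = 2 is meaningless."""


@dataclass(frozen=True)
class FeatureRecord:
    """Graph-parameter sextet of one burst (g_* from G, kg_* from K(G))."""

    burst_id: int
    g_max_degree: int
    g_clique_number: int
    g_n_maxcliques: int
    kg_max_degree: int
    kg_clique_number: int
    kg_n_maxcliques: int

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of a two-cluster K-means run.

    ``centroids`` maps each label to its cluster mean in raw (unscaled)
    feature units, in the order of ``feature_pair``.
    """

    labels: tuple[str, ...]
    centroids: dict
    feature_pair: tuple[str, str]
    graph_source: str
    seed: int
    standardized: bool


def extract_features(
    segments: list[BurstSegment], percent: float = 5.0
) -> list[FeatureRecord]:
    """Compute the six graph parameters for every burst segment.

    Each segment is decimated to ``percent`` of its sampling frequency
    before the visibility graph is built.  Segments shorter than two
    samples after decimation are skipped with a warning (their burst ids
    are simply absent from the output).
    """
    records: list[FeatureRecord] = []
    for burst_id, seg in enumerate(segments):
        reduced = downsample(seg.points, percent)
        if len(reduced) < 2:
            logger.warning(
                "skipping burst %d: only %d sample(s) left after decimation",
                burst_id,
                len(reduced),
            )
            continue
        g = visibility_graph(reduced)
        kg, g_cliques = maxclique_graph(g)
        gp = graph_parameters(g, cliques=g_cliques)
        kgp = graph_parameters(kg)
        records.append(
            FeatureRecord(
                burst_id=burst_id,
                g_max_degree=gp.max_degree,
                g_clique_number=gp.clique_number,
                g_n_maxcliques=gp.n_maxcliques,
                kg_max_degree=kgp.max_degree,
                kg_clique_number=kgp.clique_number,
                kg_n_maxcliques=kgp.n_maxcliques,
            )
        )
    return records


def features_to_frame(
    records: list[FeatureRecord], labels: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Tabulate records (one row per burst) with an optional label column."""
    frame = pd.DataFrame([r.as_dict() for r in records])
    if labels is not None:
        frame["label"] = list(labels)
    return frame


def _graph_source(pair: tuple[str, str]) -> str:
    if all(f.startswith("kg_") for f in pair):
        return "maxclique"
    if all(f.startswith("g_") for f in pair):
        return "visibility"
    return "mixed"


def kmeans_classify(
    features: list[FeatureRecord],
    feature_pair: tuple[str, str] = DEFAULT_FEATURE_PAIR,
    seed: int = 0,
    standardize: bool = True,
) -> ClassificationResult:
    """Partition bursts into sigh / non-sigh by K-means on a feature pair.

    Lloyd's algorithm with k = 2, k-means++ initialisation seeded by
    ``seed``, 10 restarts keeping the lowest within-cluster sum of
    squares, at most 300 iterations.

    With ``standardize`` on (the default) clustering happens on z-scores
    of the log10-transformed features.  All six graph parameters are
    positive counts, and the maxclique counts in particular are heavy-
    tailed, spanning orders of magnitude across bursts; on the raw scale
    a single extreme burst dominates the within-cluster sum of squares
    and K-means degenerates to splitting off that one point.  The log
    scale makes cluster separation reflect ratios rather than absolute
    counts.  Pass ``standardize=False`` to cluster in raw space.
    """
    for f in feature_pair:
        if f not in FEATURE_FIELDS:
            raise ValueError(f"unknown feature {f!r}; choose from {FEATURE_FIELDS}")
    if len(features) < 2:
        raise ValueError("need at least 2 feature records to form 2 clusters")
    x = np.array(
        [[getattr(r, f) for f in feature_pair] for r in features], dtype=float
    )
    if np.all(x == x[0]):
        raise DegenerateFeatureError(
            "degenerate feature cloud: all bursts have identical features"
        )
    if standardize:
        logx = np.log10(np.maximum(x, 1.0))
        sd = logx.std(axis=0)
        sd[sd == 0] = 1.0
        x_fit = (logx - logx.mean(axis=0)) / sd
    else:
        x_fit = x
    km = KMeans(n_clusters=2, n_init=10, max_iter=300, random_state=seed)
    assignments = km.fit_predict(x_fit)
    raw_centroids = np.array([x[assignments == c].mean(axis=0) for c in (0, 1)])
    count_coords = [
        i for i, f in enumerate(feature_pair) if f.endswith("n_maxcliques")
    ]
    if count_coords:
        # the cluster richer in maxcliques is the sigh cluster
        sigh_cluster = int(np.argmax(raw_centroids[:, count_coords[0]]))
    else:
        sigh_cluster = int(np.argmax(np.linalg.norm(raw_centroids, axis=1)))
    labels = tuple(SIGH if a == sigh_cluster else NON_SIGH for a in assignments)
    centroids = {
        SIGH: raw_centroids[sigh_cluster].tolist(),
        NON_SIGH: raw_centroids[1 - sigh_cluster].tolist(),
    }
    return ClassificationResult(
        labels=labels,
        centroids=centroids,
        feature_pair=tuple(feature_pair),
        graph_source=_graph_source(tuple(feature_pair)),
        seed=seed,
        standardized=standardize,
    )


def classification_counts(result: ClassificationResult) -> tuple[int, int]:
    """(n_sigh, n_non_sigh); the two always sum to the number of bursts."""
    n_sigh = sum(1 for lab in result.labels if lab == SIGH)
    return n_sigh, len(result.labels) - n_sigh
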