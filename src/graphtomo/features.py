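"""The twelve network order parameters of a contact graph.

Each graph is summarized by a fixed-order vector of scalar descriptors
spanning three vantage points — whole-graph topology (nodes, edges,
density, diameter, path length, clustering), node centrality (closeness,
eigenvector, betweenness), and mesoscale organization (degree
assortativity, clique number, community count). These are the features
compared by the similarity score.

Conventions chosen for degenerate cases (the score needs every entry
finite):

* diameter and average path length are computed on the largest connected
  component; a single-node component gives 0 for both;
* betweenness is the unnormalized Brandes count over unordered node pairs;
* eigenvector centrality of an edgeless graph is 0;
* degree assortativity with zero degree variance (e.g. regular graphs) is
  reported as 0;
* every isolated node counts as its own community.
"""
from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .contact import ProteinGraph

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "n_nodes",
    "n_edges",
    "density",
    "diameter",
    "avg_path_length",
    "avg_clustering",
    "max_closeness",
    "max_eigenvector",
    "max_betweenness",
    "assortativity",
    "max_clique",
    "n_communities",
)


class FeatureVector(NamedTuple):
    n_nodes: float
    n_edges: float
    density: float
    diameter: float
    avg_path_length: float
    avg_clustering: float
    max_closeness: float
    max_eigenvector: float
    max_betweenness: float
    assortativity: float
    max_clique: float
    n_communities: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _as_nx(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, ProteinGraph) else graph


def betweenness_all(graph) -> dict:
    """Unnormalized betweenness: shortest paths through each node, counted
    once per unordered pair of other nodes, with equal-length alternatives
    split fractionally (Brandes accounting)."""
    return nx.betweenness_centrality(_as_nx(graph), normalized=False)


def communities_cnm(graph) -> list[set]:
    """Greedy modularity (Clauset-Newman-Moore) communities; isolated nodes
    each form their own community."""
    g = _as_nx(graph)
    if g.number_of_edges() == 0:
        return [{v} for v in g.nodes]
    return [set(c) for c in nx.community.greedy_modularity_communities(g)]


def _max_eigenvector(g: nx.Graph) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    if not nx.is_connected(g):
        # the dominant eigenvector lives on (one of) the strongest
        # component(s); restrict to the giant component for a well-defined,
        # deterministic value
        g = g.subgraph(max(nx.connected_components(g), key=len))
        if g.number_of_edges() == 0:
            return 0.0
    try:
        cent = nx.eigenvector_centrality(g, max_iter=1000, tol=1e-8)
    except nx.PowerIterationFailedConvergence:
        if g.number_of_nodes() > 2000:
            raise
        cent = nx.eigenvector_centrality_numpy(g)
    return float(max(cent.values()))


def compute_features(graph) -> FeatureVector:
    """Compute all twelve order parameters of one graph (deterministic)."""
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot featurize an empty graph")
    m = g.number_of_edges()

    giant = g.subgraph(max(nx.connected_components(g), key=len))
    if giant.number_of_nodes() > 1:
        diameter = float(nx.diameter(giant))
        apl = float(nx.average_shortest_path_length(giant))
    else:
        diameter = 0.0
        apl = 0.0

    assort = 0.0
    if m > 0:
        with np.errstate(invalid="ignore", divide="ignore"):
            a = nx.degree_assortativity_coefficient(g)
        if np.isfinite(a):
            assort = float(a)
        else:
            logger.warning("degree assortativity undefined (zero variance); using 0")

    return FeatureVector(
        n_nodes=float(n),
        n_edges=float(m),
        density=float(nx.density(g)),
        diameter=diameter,
        avg_path_length=apl,
        avg_clustering=float(nx.average_clustering(g)) if n > 0 else 0.0,
        max_closeness=float(max(nx.closeness_centrality(g).values())),
        max_eigenvector=_max_eigenvector(g),
        max_betweenness=float(max(betweenness_all(g).values())),
        assortativity=assort,
        max_clique=float(nx.max_weight_clique(g, weight=None)[1]),
        n_communities=float(len(communities_cnm(g))),
    )


def features_frame(graphs: Iterable, ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Feature table: one row per graph, twelve named columns."""
    graphs = list(graphs)
    if ids is None:
        ids = [getattr(g, "source_id", "") or f"graph_{k}" for k, g in enumerate(graphs)]
    rows = [compute_features(g).as_array() for g in graphs]
    return pd.DataFrame(rows, index=list(ids), columns=list(FEATURE_NAMES))


class NetworkFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: graphs in, (n, 12) feature matrix out.

    Accepts a list of :class:`~graphtomo.contact.ProteinGraph` or bare
    ``networkx.Graph`` objects and returns the order-parameter matrix, so
    graph featurization can sit at the head of an sklearn pipeline.
    """

    def fit(self, X, y=None):  # noqa: D102 - nothing to learn
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack([compute_features(g).as_array() for g in X])

    def get_feature_names_out(self, input_features=None):
        return np.array(FEATURE_NAMES, dtype=object)
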