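import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.base import clone

import graphtomo as gt
from graphtomo.features import (FEATURE_NAMES, NetworkFeatureExtractor,
                                betweenness_all, communities_cnm,
                                compute_features)


def worked_graph():
    """Five nodes A..E with edges AB, AC, BC, BE, DE."""
    return nx.Graph([("A", "B"), ("A", "C"), ("B", "C"), ("B", "E"), ("D", "E")])


# ---------------------------------------------------------------------------
# independent oracles

def floyd_warshall_paths(g):
    nodes = list(g.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for u, v in g.edges:
        dist[idx[u], idx[v]] = dist[idx[v], idx[u]] = 1.0
    for k in range(n):
        dist = np.minimum(dist, dist[:, k:k + 1] + dist[k:k + 1, :])
    return dist


def brute_betweenness(g):
    """Count shortest paths through each node by explicit enumeration."""
    counts = dict.fromkeys(g.nodes, 0.0)
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for p in paths:
            for v in p[1:-1]:
                counts[v] += 1.0 / len(paths)
    return counts


def brute_best_partition_n_communities(g):
    """Exhaustive modularity maximization over all partitions (tiny n)."""
    nodes = list(g.nodes)

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
            yield part + [[head]]

    best, best_q = None, -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, [set(p) for p in part])
        if q > best_q:
            best, best_q = part, q
    return len(best)


class TestWorkedExample:
    def test_betweenness_degree_clique_and_path(self):
        g = worked_graph()
        bc = betweenness_all(g)
        assert bc["B"] == 4
        assert max(bc.values()) == 4
        assert g.degree("B") == 3
        fv = compute_features(g)
        assert fv.max_betweenness == 4
        assert fv.max_clique == 3
        assert nx.shortest_path_length(g, "D", "A") == 3


class TestKnownGraphs:
    def test_complete_graph_identities(self):
        fv = compute_features(nx.complete_graph(5))
        assert fv.n_nodes == 5 and fv.n_edges == 10
        assert fv.density == 1.0 and fv.diameter == 1.0
        assert fv.avg_path_length == 1.0 and fv.avg_clustering == 1.0
        assert fv.max_clique == 5 and fv.max_betweenness == 0.0
        assert fv.n_communities == 1

    def test_path_graph_metrics(self):
        fv = compute_features(nx.path_graph(4))
        assert fv.diameter == 3
        assert fv.avg_path_length == pytest.approx(10 / 6)
        assert fv.density == pytest.approx(0.5)

    def test_star_betweenness(self):
        bc = betweenness_all(nx.star_graph(4))
        assert bc[0] == 6  # all C(4,2) pairs route through the hub

    def test_edgeless_graph_conventions(self):
        fv = compute_features(nx.empty_graph(4))
        assert fv.n_communities == 4
        assert fv.diameter == 0 and fv.avg_path_length == 0
        assert fv.max_eigenvector == 0.0 and fv.assortativity == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            compute_features(nx.Graph())


class TestCommunities:
    def test_two_cliques_bridged(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        assert len(communities_cnm(g)) == 2

    def test_matches_exhaustive_modularity_on_tiny_graph(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_edge(0, 3)
        assert len(communities_cnm(g)) == brute_best_partition_n_communities(g)

    def test_complete_graph_single_community(self):
        assert len(communities_cnm(nx.complete_graph(5))) == 1


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", range(6))
    def test_distance_and_betweenness_oracles_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        g = nx.gnp_random_graph(n, 0.4, seed=seed)
        fv = compute_features(g)
        dist = floyd_warshall_paths(g)
        comps = list(nx.connected_components(g))
        giant = max(comps, key=len)
        if len(giant) > 1:
            ii = [i for i, v in enumerate(g.nodes) if v in giant]
            sub = dist[np.ix_(ii, ii)]
            assert fv.diameter == sub.max()
            off = sub[~np.eye(len(ii), dtype=bool)]
            assert fv.avg_path_length == pytest.approx(off.mean())
        bb = brute_betweenness(g)
        nx_bc = betweenness_all(g)
        for v in g.nodes:
            assert nx_bc[v] == pytest.approx(bb[v])
        assert fv.max_betweenness == pytest.approx(max(bb.values()))

    @pytest.mark.parametrize("seed", range(4))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = nx.gnp_random_graph(10, 0.45, seed=seed)
        perm = rng.permutation(10)
        h = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(10)})
        assert np.allclose(compute_features(g).as_array(),
                           compute_features(h).as_array())


class TestFeatureVector:
    def test_fixed_order_and_length(self):
        fv = compute_features(nx.complete_graph(4))
        assert len(FEATURE_NAMES) == 12
        assert fv._fields == FEATURE_NAMES
        assert fv.as_array().shape == (12,)
        assert np.all(np.isfinite(fv.as_array()))

    def test_rigid_motion_invariance_through_contact_graph(self):
        s = gt.make_helix(25)
        ref = compute_features(gt.build_contact_graph(s, 9.0)).as_array()
        R = gt.random_rotation(3)
        moved = gt.CaStructure(chain_ids=s.chain_ids,
                               residue_indices=s.residue_indices,
                               coords=s.coords @ R.T + [11.0, -5.0, 2.0])
        got = compute_features(gt.build_contact_graph(moved, 9.0)).as_array()
        assert np.allclose(ref, got)


class TestNetworkFeatureExtractor:
    def test_transform_shape_and_names(self):
        ex = NetworkFeatureExtractor()
        X = ex.fit_transform([nx.complete_graph(4), nx.path_graph(5)])
        assert X.shape == (2, 12)
        assert list(ex.get_feature_names_out()) == list(FEATURE_NAMES)

    def test_sklearn_clonable(self):
        ex = NetworkFeatureExtractor()
        assert isinstance(clone(ex), NetworkFeatureExtractor)
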