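import networkx as nx
import numpy as np
import pytest

from fungpcr.cluster import (
    MarkovClustering,
    build_graph,
    cluster_domain_summary,
    mcl,
    write_clusters,
)
from fungpcr.io_formats import BlastHit, PfamAnnotation


def hit(q, s, evalue=1e-10):
    return BlastHit(q, s, evalue, 50.0, 1, 90, 1, 90, 100, 100)


def reference_mcl_partition(adjacency, inflation=2.0):
    """Independent, deliberately plain MCL iteration used as an oracle.

    Written with explicit elementwise loops over the textbook recipe
    (add self-loops, column-normalize, square, inflate, renormalize) and a
    connected-components reading of the limit matrix.
    """
    n = len(adjacency)
    M = [[float(adjacency[i][j]) for j in range(n)] for i in range(n)]
    for i in range(n):
        M[i][i] = max(max(row[i] for row in M), 1e-12)
    for _ in range(200):
        for j in range(n):  # column normalize
            s = sum(M[i][j] for i in range(n))
            for i in range(n):
                M[i][j] /= s
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)]
              for i in range(n)]
        new = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        for j in range(n):
            s = sum(new[i][j] for i in range(n))
            for i in range(n):
                new[i][j] /= s
        delta = max(abs(new[i][j] - M[i][j])
                    for i in range(n) for j in range(n))
        M = new
        if delta < 1e-10:
            break
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if M[i][j] > 1e-6:
                g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestBuildGraph:
    def test_reciprocal_pair_single_edge(self):
        g = build_graph([hit("a", "b"), hit("b", "a")])
        assert g.number_of_edges() == 1

    def test_self_hit_gives_isolated_node(self):
        g = build_graph([hit("a", "a")])
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_asymmetric_weight_is_max(self):
        g = build_graph([hit("a", "b", 1e-10), hit("b", "a", 1e-20)])
        assert g["a"]["b"]["weight"] == pytest.approx(20.0)

    def test_evalue_weight_capped(self):
        g = build_graph([hit("a", "b", 0.0)])
        assert g["a"]["b"]["weight"] == 200.0


class TestMcl:
    def test_disjoint_triangles_two_clusters(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            g.add_edge(a, b, weight=1.0)
        clustering = mcl(g)
        assert {frozenset(c) for c in clustering.clusters} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})}

    def test_edgeless_nodes_are_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abcde")
        assert len(mcl(g)) == 5

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mcl(nx.Graph())

    def test_barbell_matches_reference_implementation(self):
        # two K4s joined by one bridge edge
        g = nx.Graph()
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3),
                 (4, 5), (4, 6), (4, 7), (5, 6), (5, 7), (6, 7), (3, 4)]
        for a, b in edges:
            g.add_edge(a, b, weight=1.0)
        ours = {frozenset(c) for c in mcl(g).clusters}
        adjacency = nx.to_numpy_array(g, nodelist=range(8))
        assert ours == reference_mcl_partition(adjacency)
        assert ours == {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}

    def test_partition_and_order_invariance(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(20, 0.2, seed=5)
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.uniform(0.5, 2.0))
        clustering = mcl(g)
        nodes = set().union(*clustering.clusters)
        assert nodes == set(g.nodes)
        assert sum(len(c) for c in clustering.clusters) == g.number_of_nodes()
        relabeled = nx.relabel_nodes(g, {n: f"z{n}" for n in g.nodes})
        clustering2 = mcl(relabeled)
        mapped = {frozenset(f"z{n}" for n in c) for c in clustering.clusters}
        assert mapped == {frozenset(c) for c in clustering2.clusters}

    def test_clusters_within_connected_components(self):
        g = nx.Graph()
        for a, b in [(0, 1), (1, 2), (3, 4)]:
            g.add_edge(a, b, weight=1.0)
        comps = list(nx.connected_components(g))
        for cluster in mcl(g).clusters:
            assert any(cluster <= comp for comp in comps)

    def test_higher_inflation_never_coarsens(self):
        g = nx.caveman_graph(3, 4)
        for a, b in g.edges:
            g[a][b]["weight"] = 1.0
        # add light bridges between cliques
        g.add_edge(3, 4, weight=0.3)
        g.add_edge(7, 8, weight=0.3)
        sizes = []
        for inflation in (1.2, 2.0, 4.0):
            clustering = mcl(g, inflation=inflation)
            sizes.append(max(len(c) for c in clustering.clusters))
        assert sizes == sorted(sizes, reverse=True)

    def test_estimator_api(self):
        A = np.array([[0, 1, 1, 0], [1, 0, 1, 0], [1, 1, 0, 0],
                      [0, 0, 0, 0]], dtype=float)
        est = MarkovClustering().fit(A)
        assert est.labels_.shape == (4,)
        assert est.labels_[0] == est.labels_[1] == est.labels_[2]
        assert est.labels_[3] != est.labels_[0]
        assert est.converged_
        assert MarkovClustering().get_params()["inflation"] == 2.0


class TestDomainSummary:
    def two_cluster_fixture(self):
        from fungpcr.cluster import Clustering
        return Clustering(clusters=(
            frozenset({"a", "b", "c", "d"}), frozenset({"e", "f"})))

    def test_dominant_fraction(self):
        annots = [PfamAnnotation(s, "DUF6534", "PF20143", 1e-9)
                  for s in ("a", "b", "c")]
        summary = cluster_domain_summary(self.two_cluster_fixture(), annots)
        assert summary[0].dominant_domain == "DUF6534"
        assert summary[0].dominant_fraction == 0.75
        assert summary[0].n_no_domain == 1

    def test_unannotated_cluster(self):
        summary = cluster_domain_summary(self.two_cluster_fixture(), [])
        assert summary[1].dominant_domain is None
        assert summary[1].dominant_fraction == 0.0

    def test_tie_lexicographic_and_flagged(self):
        annots = [
            PfamAnnotation("a", "Zeta", "PF00002", 1e-9),
            PfamAnnotation("b", "Zeta", "PF00002", 1e-9),
            PfamAnnotation("c", "Alpha", "PF00001", 1e-9),
            PfamAnnotation("d", "Alpha", "PF00001", 1e-9),
        ]
        summary = cluster_domain_summary(self.two_cluster_fixture(), annots)
        assert summary[0].dominant_domain == "Alpha"
        assert summary[0].tie is True


def test_write_clusters(tmp_path):
    from fungpcr.cluster import Clustering
    clustering = Clustering(clusters=(frozenset({"b", "a"}),
                                      frozenset({"c"})))
    out = tmp_path / "clusters.tsv"
    write_clusters(clustering, out)
    assert out.read_text() == "a\tb\nc\n"
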