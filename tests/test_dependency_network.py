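"""Word-type dependency networks: construction, summaries, node topology."""

import itertools

import networkx as nx
import numpy as np
import pytest

from synspeech.dependency_network import (
    DependencyNetwork,
    build_network,
    network_difference,
    node_metrics,
    pajek_summary,
    weighted_degrees,
)
from synspeech.synthetic_treebank import ad_profile, generate_corpus
from synspeech.treebank_io import Treebank, TreebankError

from conftest import make_sentence


def brute_force_metrics(graph: nx.Graph):
    """Exhaustive shortest-path oracle for betweenness/closeness/clustering.

    Counts shortest paths by BFS-level dynamic programming per source and
    combines pair counts directly — independent of the Brandes accumulation
    used by networkx.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        d = {s: 0}
        counts = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in graph.neighbors(u):
                    if v not in d:
                        d[v] = d[u] + 1
                        counts[v] = 0
                        nxt.append(v)
                    if d[v] == d[u] + 1:
                        counts[v] += counts[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = counts

    betweenness = {}
    scale = (n - 1) * (n - 2) / 2 if n > 2 else 1
    for v in nodes:
        total = 0.0
        for s, t in itertools.combinations(nodes, 2):
            if v in (s, t) or t not in dist[s]:
                continue
            if v in dist[s] and dist[s][v] + dist[v][t] == dist[s][t]:
                total += sigma[s][v] * sigma[v][t] / sigma[s][t]
        betweenness[v] = total / scale

    closeness = {}
    for v in nodes:
        reachable = [u for u in dist[v] if u != v]
        if not reachable:
            closeness[v] = 0.0
            continue
        r = len(reachable)
        total = sum(dist[v][u] for u in reachable)
        closeness[v] = (r / (n - 1)) * (r / total)

    clustering = {}
    for v in nodes:
        neigh = list(graph.neighbors(v))
        k = len(neigh)
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(1 for a, b in itertools.combinations(neigh, 2)
                    if graph.has_edge(a, b))
        clustering[v] = 2 * links / (k * (k - 1))
    return betweenness, closeness, clustering


class TestBuildNetwork:
    def test_single_sentence(self):
        s = make_sentence([
            ("the", "DET", 2, "det"),
            ("boy", "NOUN", 3, "nsubj"),
            ("runs", "VERB", 0, "root"),
        ])
        net = build_network(Treebank([s]))
        assert net.n == 3 and net.m == 2
        assert net.arcs == {("boy", "the", "det"): 1, ("runs", "boy", "nsubj"): 1}

    def test_repeated_dependency_accumulates_weight(self):
        s = make_sentence([
            ("the", "DET", 2, "det"), ("boy", "NOUN", 0, "root"),
        ])
        net = build_network(Treebank([s, s]))
        assert net.m == 1
        assert net.arcs[("boy", "the", "det")] == 2

    def test_root_and_punct_links_excluded(self, sample_treebank):
        net = build_network(sample_treebank)
        assert all("." not in key[:2] for key in net.arcs)
        assert net.total_weight == 9  # 11 tokens - root - punct link

    def test_counts_match_brute_force_on_generated_corpus(self):
        corpus = generate_corpus(ad_profile(), 123)
        tb = Treebank(corpus.treebank.sentences[:500])
        net = build_network(tb)
        types = set()
        triples = {}
        n_links = 0
        for s in tb.sentences:
            for t in s.tokens:
                if t.governor == 0 or t.is_punct:
                    continue
                gov = s.tokens[t.governor - 1]
                if gov.is_punct:
                    continue
                types.add(t.surface_form.lower())
                types.add(gov.surface_form.lower())
                key = (gov.surface_form.lower(), t.surface_form.lower(), t.relation)
                triples[key] = triples.get(key, 0) + 1
                n_links += 1
        assert net.n == len(types)
        assert net.m == len(triples)
        assert net.arcs == triples
        assert net.total_weight == n_links  # conservation

    def test_relabeling_permutes_but_preserves_metrics(self):
        corpus = generate_corpus(ad_profile(), 5)
        tb = Treebank(corpus.treebank.sentences[:80])
        net = build_network(tb)
        renamed = DependencyNetwork(
            vertices=[f"x_{v}" for v in net.vertices],
            arcs={(f"x_{g}", f"x_{d}", r): w for (g, d, r), w in net.arcs.items()},
        )
        m1, m2 = node_metrics(net), node_metrics(renamed)
        for attr in ("betweenness", "closeness", "clustering"):
            vals1 = sorted(getattr(m1, attr).values())
            vals2 = sorted(getattr(m2, attr).values())
            assert np.allclose(vals1, vals2)


class TestPajekSummary:
    @pytest.mark.parametrize("n,m,avg,dens", [
        (1076, 13591, 25.26208178, 0.02347777),
        (1136, 15979, 28.13204225, 0.02476412),
        (107, 200, 3.73831776, 0.03493755),
    ])
    def test_printed_summary_values(self, n, m, avg, dens):
        stats = pajek_summary(n, m)
        assert stats["average_degree"] == pytest.approx(avg, abs=5e-9)
        assert stats["density_loops_allowed"] == pytest.approx(dens, abs=5e-9)

    def test_triangle(self):
        net = DependencyNetwork(
            vertices=["a", "b", "c"],
            arcs={("a", "b", "x"): 1, ("b", "c", "x"): 1, ("c", "a", "x"): 1},
        )
        stats = pajek_summary(net)
        assert stats["average_degree"] == 2.0
        assert stats["density_loops_allowed"] == pytest.approx(2 / 3)

    def test_density_degree_consistency(self):
        corpus = generate_corpus(ad_profile(), 9)
        net = build_network(Treebank(corpus.treebank.sentences[:100]))
        stats = pajek_summary(net)
        assert stats["density_loops_allowed"] == pytest.approx(
            stats["average_degree"] / net.n
        )

    def test_empty_network_rejected(self):
        with pytest.raises(TreebankError):
            pajek_summary(DependencyNetwork())


class TestNodeMetrics:
    def path3(self):
        return DependencyNetwork(
            vertices=["a", "b", "c"],
            arcs={("a", "b", "x"): 1, ("b", "c", "x"): 1},
        )

    def test_path_graph_closed_form(self):
        m = node_metrics(self.path3())
        assert m.betweenness["b"] == pytest.approx(1.0)
        assert m.closeness["b"] == pytest.approx(1.0)
        assert all(v == 0 for v in m.clustering.values())

    def test_triangle_closed_form(self):
        net = DependencyNetwork(
            vertices=["a", "b", "c"],
            arcs={("a", "b", "x"): 1, ("b", "c", "x"): 1, ("c", "a", "x"): 1},
        )
        m = node_metrics(net)
        assert all(v == pytest.approx(1.0) for v in m.clustering.values())
        assert all(v == 0 for v in m.betweenness.values())

    def test_clustering_zero_below_degree_2(self):
        m = node_metrics(self.path3())
        assert m.clustering["a"] == 0 and m.clustering["c"] == 0

    @pytest.mark.parametrize("n,p,seed", [
        (n, p, seed)
        for n in (4, 5, 6, 7, 8)
        for p in (0.3, 0.5, 0.8)
        for seed in (0, 1)
    ])
    def test_small_random_graphs_match_exhaustive_oracle(self, n, p, seed):
        graph = nx.gnp_random_graph(n, p, seed=seed)
        arcs = {(f"v{u}", f"v{v}", "x"): 1 for u, v in graph.edges}
        net = DependencyNetwork(vertices=[f"v{i}" for i in range(n)], arcs=arcs)
        m = node_metrics(net)
        skeleton = net.undirected_skeleton()
        bw, cl, cc = brute_force_metrics(skeleton)
        for v in net.vertices:
            assert m.betweenness[v] == pytest.approx(bw[v], abs=1e-12)
            assert m.closeness[v] == pytest.approx(cl[v], abs=1e-12)
            assert m.clustering[v] == pytest.approx(cc[v], abs=1e-12)

    def test_metric_ranges(self):
        corpus = generate_corpus(ad_profile(), 17)
        net = build_network(Treebank(corpus.treebank.sentences[:120]))
        m = node_metrics(net)
        assert all(v >= 0 for v in m.betweenness.values())
        assert all(0 <= v <= 1 for v in m.closeness.values())
        assert all(0 <= v <= 1 for v in m.clustering.values())


class TestWeightedDegrees:
    def test_incident_weights_sum(self):
        net = DependencyNetwork(
            vertices=["a", "b", "c"],
            arcs={("a", "b", "x"): 2, ("c", "a", "y"): 3},
        )
        ranked = dict(weighted_degrees(net, 3))
        assert ranked["a"] == 5

    def test_top_1_is_global_maximum(self):
        net = DependencyNetwork(
            vertices=["a", "b", "c"],
            arcs={("a", "b", "x"): 2, ("c", "a", "y"): 3},
        )
        assert weighted_degrees(net, 1)[0] == ("a", 5)

    def test_planted_expletive_hub(self):
        """A vertex carrying 31 incident weight ranks first with value 31."""
        arcs = {("there", f"w{i}", "expl"): 1 for i in range(15)}
        arcs.update({(f"w{i}", "there", "nsubj"): 1 for i in range(15, 31)})
        others = {(f"w{i}", f"w{i+1}", "x"): 1 for i in range(0, 10, 2)}
        arcs.update(others)
        vertices = ["there"] + [f"w{i}" for i in range(31)]
        net = DependencyNetwork(vertices=vertices, arcs=arcs)
        top = weighted_degrees(net, 1)[0]
        assert top == ("there", 31)

    def test_tie_broken_by_label(self):
        net = DependencyNetwork(
            vertices=["b", "a"],
            arcs={("b", "a", "x"): 1},
        )
        assert [v for v, _ in weighted_degrees(net, 2)] == ["a", "b"]


class TestNetworkDifference:
    def nets(self):
        a = DependencyNetwork(
            vertices=["x", "y", "z"],
            arcs={("x", "y", "r1"): 5, ("y", "z", "r2"): 2, ("x", "z", "r3"): 7},
        )
        b = DependencyNetwork(
            vertices=["x", "y"],
            arcs={("x", "y", "r1"): 99},
        )
        return a, b

    def test_identical_networks_empty(self):
        a, _ = self.nets()
        assert network_difference(a, a).m == 0

    def test_disjoint_keys_keep_all(self):
        a, b = self.nets()
        disjoint = DependencyNetwork(vertices=["p", "q"],
                                     arcs={("p", "q", "zz"): 1})
        assert network_difference(a, disjoint).arcs == a.arcs

    def test_key_set_difference_with_weights(self):
        a, b = self.nets()
        diff = network_difference(a, b)
        expected = {k: w for k, w in a.arcs.items() if k not in b.arcs}
        assert diff.arcs == expected

    def test_top_k_keeps_heaviest(self):
        a, b = self.nets()
        diff = network_difference(a, b, top_k=1)
        assert diff.arcs == {("x", "z", "r3"): 7}
        assert diff.vertices == ["x", "z"]
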