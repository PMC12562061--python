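"""Word-type dependency networks and their topology.

A treebank is collapsed into a weighted directed network whose vertices
are lowercased word types and whose arcs are distinct
(governor type, dependent type, relation) triples weighted by occurrence
count.  Root attachments and punctuation links are excluded.

Summary statistics follow the conventions of classic network software for
directed networks: average degree 2m/n and loops-allowed density 2m/n²,
where m counts distinct arcs.  Node metrics (betweenness, closeness,
clustering) are computed on the undirected simple skeleton — directions
and weights dropped, parallel arcs merged, self-loops ignored:

* betweenness — shortest-path betweenness normalised by (n−1)(n−2)/2;
* closeness — per-component normalised (Wasserman–Faust):
  (r/(n−1)) · (r/Σd), with r the number of reachable vertices;
* clustering — 2·(edges among neighbours)/(k(k−1)), zero for degree < 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .treebank_io import Treebank, TreebankError

__all__ = [
    "DependencyNetwork",
    "NodeMetrics",
    "build_network",
    "pajek_summary",
    "node_metrics",
    "weighted_degrees",
    "network_difference",
]

ArcKey = tuple[str, str, str]  # (governor type, dependent type, relation)


@dataclass
class DependencyNetwork:
    """Weighted directed word-type graph; vertex order is first-seen."""

    vertices: list[str] = field(default_factory=list)
    arcs: dict[ArcKey, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.vertices)
        for (gov, dep, _), weight in self.arcs.items():
            if weight < 1:
                raise TreebankError(f"arc weight must be >= 1, got {weight}")
            if gov not in known or dep not in known:
                raise TreebankError(f"arc ({gov!r}, {dep!r}) references unknown vertex")

    @property
    def n(self) -> int:
        """Vertex count."""
        return len(self.vertices)

    @property
    def m(self) -> int:
        """Line count: number of distinct arcs."""
        return len(self.arcs)

    @property
    def total_weight(self) -> int:
        return sum(self.arcs.values())

    def undirected_skeleton(self) -> nx.Graph:
        """Simple undirected graph: directions/weights dropped, loops removed."""
        graph = nx.Graph()
        graph.add_nodes_from(self.vertices)
        for gov, dep, _ in self.arcs:
            if gov != dep:
                graph.add_edge(gov, dep)
        return graph


@dataclass
class NodeMetrics:
    """Per-vertex topology values on the undirected skeleton."""

    degree: dict[str, int]
    weighted_degree: dict[str, float]
    betweenness: dict[str, float]
    closeness: dict[str, float]
    clustering: dict[str, float]


def build_network(treebank: Treebank) -> DependencyNetwork:
    """Collapse a treebank into its word-type dependency network.

    One arc per distinct (governor type, dependent type, relation) with
    weight = number of occurrences; root and punctuation links excluded.
    Word types are lowercased surface forms (clitics such as "'s" keep
    their own vertex).
    """
    vertices: list[str] = []
    seen: set[str] = set()
    arcs: dict[ArcKey, int] = {}
    for sentence in treebank.sentences:
        for token in sentence.tokens:
            if token.governor == 0 or token.is_punct:
                continue
            governor = sentence.tokens[token.governor - 1]
            if governor.is_punct:
                continue
            gov_type = governor.surface_form.lower()
            dep_type = token.surface_form.lower()
            for label in (gov_type, dep_type):
                if label not in seen:
                    seen.add(label)
                    vertices.append(label)
            key = (gov_type, dep_type, token.relation)
            arcs[key] = arcs.get(key, 0) + 1
    return DependencyNetwork(vertices=vertices, arcs=arcs)


def pajek_summary(network_or_n, m: int | None = None) -> dict[str, float]:
    """Average degree and loops-allowed density.

    Accepts either a :class:`DependencyNetwork` or an explicit (n, m) pair
    as printed in network-software summary panels.  average_degree = 2m/n;
    density_loops_allowed = 2m/n².
    """
    if isinstance(network_or_n, DependencyNetwork):
        n, m = network_or_n.n, network_or_n.m
    else:
        n = int(network_or_n)
        if m is None:
            raise TypeError("m is required when n is given as an integer")
    if n < 1:
        raise TreebankError("network has no vertices")
    return {
        "average_degree": 2 * m / n,
        "density_loops_allowed": 2 * m / (n * n),
    }


def node_metrics(network: DependencyNetwork) -> NodeMetrics:
    """Betweenness, closeness, clustering, degree and weighted degree.

    Topology metrics are computed on the undirected simple skeleton;
    weighted degree sums the weights of all incident arcs (in + out,
    self-loops counted twice, once per endpoint).
    """
    if network.n < 2:
        raise TreebankError("node metrics need at least 2 vertices")
    skeleton = network.undirected_skeleton()
    betweenness = nx.betweenness_centrality(skeleton, normalized=True)
    closeness = nx.closeness_centrality(skeleton, wf_improved=True)
    clustering = nx.clustering(skeleton)
    weighted: dict[str, float] = {v: 0.0 for v in network.vertices}
    for (gov, dep, _), weight in network.arcs.items():
        weighted[gov] += weight
        weighted[dep] += weight
    return NodeMetrics(
        degree=dict(skeleton.degree()),
        weighted_degree=weighted,
        betweenness=betweenness,
        closeness=closeness,
        clustering=clustering,
    )


def weighted_degrees(
    network: DependencyNetwork, top_k: int
) -> list[tuple[str, float]]:
    """Top-k vertices by weighted degree (sum of incident arc weights).

    Ties are broken by vertex label ascending, for determinism.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    weighted: dict[str, float] = {v: 0.0 for v in network.vertices}
    for (gov, dep, _), weight in network.arcs.items():
        weighted[gov] += weight
        weighted[dep] += weight
    ranked = sorted(weighted.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k]


def network_difference(
    a: DependencyNetwork, b: DependencyNetwork, top_k: int | None = None
) -> DependencyNetwork:
    """Arcs of ``a`` whose (governor, dependent, relation) key is absent
    from ``b``, retaining ``a``'s weights.

    With finite ``top_k``, only the ``top_k`` heaviest such arcs are kept
    (weight descending, key ascending on ties).  Vertices are restricted
    to the endpoints of the retained arcs, preserving ``a``'s order.
    """
    diff = {key: w for key, w in a.arcs.items() if key not in b.arcs}
    if top_k is not None:
        kept = sorted(diff.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        diff = dict(kept)
    endpoints = {gov for gov, _, _ in diff} | {dep for _, dep, _ in diff}
    vertices = [v for v in a.vertices if v in endpoints]
    return DependencyNetwork(vertices=vertices, arcs=diff)
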