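"""Network topology: the comparison-table metrics, centralities, communities
and random-graph small-world references.

Edges are treated as unweighted for path-based quantities (diameter, path
length, betweenness): correlation magnitude is a similarity, not a distance.
"Components" are connected components; "clusters" are modularity communities
found by seeded Louvain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np

__all__ = [
    "fragmentation",
    "TopologyReport",
    "summarize",
    "communities",
    "centralities",
    "annotate",
    "NodeCentrality",
    "random_reference",
    "NullReference",
    "is_small_world",
]


def fragmentation(cl: int, n: int) -> float:
    """Network fragmentation f = log(CL) / log(N).

    CL is the number of connected components and N the node count; f is 0
    for a connected graph and 1 when every node is its own component.  The
    ratio of logarithms is base-invariant.
    """
    if n < 2:
        raise ValueError("fragmentation requires at least 2 nodes")
    if not 1 <= cl <= n:
        raise ValueError("component count must lie in [1, N]")
    return math.log(cl) / math.log(n)


@dataclass
class TopologyReport:
    """The per-network metric vector of the comparison table."""

    n_nodes: int
    n_edges: int
    fragmentation: float
    average_degree: float
    diameter: int
    density: float
    modularity: float
    n_components: int
    avg_clustering_coefficient: float
    avg_path_length: float
    n_clusters: int
    n_negative_edges: int
    pct_negative_edges: float

    def to_dict(self) -> dict:
        return asdict(self)


def _negative_edge_count(net: nx.Graph) -> int:
    cnt = 0
    for _, _, d in net.edges(data=True):
        if d.get("sign") == "negative" or float(d.get("weight", 0.0)) < 0:
            cnt += 1
    return cnt


def _path_stats(net: nx.Graph) -> tuple[int, float]:
    """(diameter of the largest component, mean distance over connected pairs)."""
    comps = [net.subgraph(c) for c in nx.connected_components(net)]
    largest = max(comps, key=len)
    diameter = 0
    total = 0
    pairs = 0
    for sub in comps:
        if len(sub) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    pairs += 1
                    if sub is largest and d > diameter:
                        diameter = d
    # each unordered pair counted twice above; ratio is unaffected
    avg = total / pairs if pairs else 0.0
    return diameter, avg


def communities(net: nx.Graph, seed: int = 0):
    """Louvain modularity communities (resolution 1, unweighted, seeded).

    Returns ``(partition, Q, n_clusters)`` where ``partition`` is a list of
    node sets and Q is the Newman modularity of that partition.
    """
    if net.number_of_nodes() == 0:
        return [], 0.0, 0
    if net.number_of_edges() == 0:
        parts = [{n} for n in net.nodes]
        return parts, 0.0, len(parts)
    parts = nx.community.louvain_communities(net, weight=None, seed=seed)
    q = nx.community.modularity(net, parts, weight=None)
    return parts, float(q), len(parts)


def summarize(net: nx.Graph, modularity_seed: int = 0) -> TopologyReport:
    """Compute the full topology report for one network."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("topology summary requires at least 2 nodes")
    e = net.number_of_edges()
    cl = nx.number_connected_components(net)
    diameter, avg_path = _path_stats(net)
    clustering = nx.average_clustering(net) if e else 0.0  # degree<2 nodes count 0
    parts, q, n_clusters = communities(net, seed=modularity_seed)
    neg = _negative_edge_count(net)
    return TopologyReport(
        n_nodes=n,
        n_edges=e,
        fragmentation=fragmentation(cl, n),
        average_degree=2 * e / n,
        diameter=diameter,
        density=2 * e / (n * (n - 1)),
        modularity=q,
        n_components=cl,
        avg_clustering_coefficient=clustering,
        avg_path_length=avg_path,
        n_clusters=n_clusters,
        n_negative_edges=neg,
        pct_negative_edges=100.0 * neg / e if e else 0.0,
    )


@dataclass
class NodeCentrality:
    degree: int
    normalized_degree: float
    betweenness: float
    community_id: int


def centralities(net: nx.Graph, seed: int = 0) -> dict[str, NodeCentrality]:
    """Per-node degree, degree/E, unnormalised betweenness and community id.

    Betweenness is the exact all-pairs shortest-path accumulation on
    unweighted edges, with each unordered pair counted once.
    """
    if net.number_of_nodes() < 2:
        raise ValueError("centralities require at least 2 nodes")
    e = net.number_of_edges()
    bc = nx.betweenness_centrality(net, normalized=False)
    parts, _, _ = communities(net, seed=seed)
    comm_of = {}
    for cid, part in enumerate(parts):
        for node in part:
            comm_of[node] = cid
    return {
        n: NodeCentrality(
            degree=net.degree(n),
            normalized_degree=net.degree(n) / e if e else 0.0,
            betweenness=float(bc[n]),
            community_id=comm_of.get(n, -1),
        )
        for n in net.nodes
    }


def annotate(net: nx.Graph, seed: int = 0) -> None:
    """Attach degree/betweenness/community node attributes in place."""
    for n, c in centralities(net, seed=seed).items():
        net.nodes[n]["degree"] = c.degree
        net.nodes[n]["betweenness"] = c.betweenness
        net.nodes[n]["community"] = c.community_id


@dataclass
class NullReference:
    """Null distributions of clustering / path length / modularity over
    Erdős–Rényi G(n, m) graphs with the observed node and edge counts."""

    clustering: np.ndarray
    path_length: np.ndarray
    modularity: np.ndarray

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            "clustering": (float(self.clustering.mean()), float(self.clustering.std())),
            "path_length": (float(self.path_length.mean()), float(self.path_length.std())),
            "modularity": (float(self.modularity.mean()), float(self.modularity.std())),
        }


def random_reference(n: int, e: int, reps: int = 100, seed: int = 0) -> NullReference:
    """Metrics of ``reps`` G(n, m) random graphs with exactly n nodes, e edges."""
    if e > n * (n - 1) // 2:
        raise ValueError("edge count exceeds the complete graph")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    cc = np.empty(reps)
    pl = np.empty(reps)
    qm = np.empty(reps)
    for r in range(reps):
        s = int(rng.integers(0, 2**31 - 1))
        g = nx.gnm_random_graph(n, e, seed=s)
        cc[r] = nx.average_clustering(g) if e else 0.0
        _, pl[r] = _path_stats(g)
        _, qm[r], _ = communities(g, seed=s)
    return NullReference(clustering=cc, path_length=pl, modularity=qm)


def is_small_world(observed_clustering: float, observed_path_length: float,
                   null: NullReference, sd_factor: float = 2.0) -> bool:
    """Small-world call: clustering above the null by > 2 sd while path
    length stays within 2 sd of the null mean."""
    c_mu, c_sd = null.summary()["clustering"]
    l_mu, l_sd = null.summary()["path_length"]
    return (observed_clustering > c_mu + sd_factor * c_sd
            and abs(observed_path_length - l_mu) <= sd_factor * l_sd)
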