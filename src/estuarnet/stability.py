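"""Stability analysis: targeted node removal, fragmentation trajectories and
degree–betweenness coupling.

The attack experiments remove the top-k nodes under a ranking criterion
(abundance, degree, betweenness, or random) and record how the component
count, fragmentation f = log(CL)/log(N) and modularity respond.  Nodes that
become isolated by a removal remain in the graph and count toward CL: they
were members of the network, and losing their connections is exactly the
fragmentation being measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from . import topology
from .tables import RelAbundanceTable

__all__ = [
    "rank_nodes",
    "remove_top_k",
    "attack_trajectory",
    "AttackTrajectory",
    "AttackRound",
    "coupling",
    "CouplingResult",
    "compare_coupling",
]

CRITERIA = ("abundance", "degree", "betweenness", "random")


def _scores(net: nx.Graph, criterion: str,
            rel: RelAbundanceTable | None) -> dict[str, float]:
    if criterion == "degree":
        return {n: float(net.degree(n)) for n in net.nodes}
    if criterion == "betweenness":
        return {n: float(v) for n, v in
                nx.betweenness_centrality(net, normalized=False).items()}
    if criterion == "abundance":
        if rel is not None:
            means = dict(zip(rel.taxon_ids, rel.values.mean(axis=1)))
            missing = [n for n in net.nodes if n not in means]
            if missing:
                raise ValueError(f"nodes without abundance values: {missing[:5]}")
            return {n: float(means[n]) for n in net.nodes}
        try:
            return {n: float(net.nodes[n]["abundance"]) for n in net.nodes}
        except KeyError as exc:
            raise ValueError(
                "abundance criterion needs node 'abundance' attributes or an "
                "abundance table") from exc
    raise ValueError(f"unknown ranking criterion {criterion!r}")


def rank_nodes(net: nx.Graph, rel: RelAbundanceTable | None = None,
               criterion: str = "degree") -> list[str]:
    """Nodes in descending criterion order; ties broken by id (deterministic)."""
    scores = _scores(net, criterion, rel)
    return sorted(scores, key=lambda n: (-scores[n], str(n)))


def remove_top_k(net: nx.Graph, criterion: str = "betweenness", k: int = 10,
                 rel: RelAbundanceTable | None = None,
                 modularity_seed: int = 0) -> tuple[nx.Graph, topology.TopologyReport]:
    """Remove the k top-ranked nodes and recompute the topology report.

    Nodes isolated by the removal stay in the graph and count toward the
    component number, so CL (and f) can grow.
    """
    if k >= net.number_of_nodes():
        raise ValueError("k must be smaller than the node count")
    top = rank_nodes(net, rel=rel, criterion=criterion)[:k]
    g = net.copy()
    g.remove_nodes_from(top)
    return g, topology.summarize(g, modularity_seed=modularity_seed)


@dataclass
class AttackRound:
    removed: list[str]
    n_after: int
    cl_after: int
    f_after: float
    e_after: int
    modularity_after: float


@dataclass
class AttackTrajectory:
    criterion: str
    adaptive: bool
    rounds: list[AttackRound] = field(default_factory=list)


def attack_trajectory(net: nx.Graph, criterion: str = "betweenness",
                      rounds: int = 10, k: int = 10, adaptive: bool = True,
                      seed: int = 0,
                      rel: RelAbundanceTable | None = None) -> AttackTrajectory:
    """Iterative top-k removal, recording (N, CL, f, E, Q) after each round.

    When ``adaptive`` the ranking is recomputed on the current graph before
    every round; otherwise the original ranking is consumed in order.  The
    ``random`` criterion draws uniform nodes from the current graph using
    ``seed``.
    """
    if criterion not in CRITERIA:
        raise ValueError(f"unknown attack criterion {criterion!r}")
    if rounds < 1 or k < 1:
        raise ValueError("rounds and k must be positive")
    if rounds * k >= net.number_of_nodes():
        raise ValueError("rounds*k must be smaller than the node count")
    rng = np.random.default_rng(seed)
    g = net.copy()
    static_order: list[str] | None = None
    if criterion != "random" and not adaptive:
        static_order = rank_nodes(g, rel=rel, criterion=criterion)
    traj = AttackTrajectory(criterion=criterion, adaptive=adaptive)
    for r in range(rounds):
        if g.number_of_nodes() <= k + 1:
            warnings.warn("graph exhausted; trajectory truncated", stacklevel=2)
            break
        if criterion == "random":
            nodes = sorted(g.nodes)
            target = [nodes[i] for i in
                      rng.choice(len(nodes), size=k, replace=False)]
        elif adaptive:
            target = rank_nodes(g, rel=rel, criterion=criterion)[:k]
        else:
            assert static_order is not None
            target = static_order[r * k:(r + 1) * k]
        g.remove_nodes_from(target)
        n = g.number_of_nodes()
        cl = nx.number_connected_components(g)
        _, q, _ = topology.communities(g, seed=seed + r)
        traj.rounds.append(AttackRound(
            removed=list(target),
            n_after=n,
            cl_after=cl,
            f_after=topology.fragmentation(cl, n),
            e_after=g.number_of_edges(),
            modularity_after=q,
        ))
    return traj


@dataclass
class CouplingResult:
    """Spearman coupling between node-normalised degree and betweenness."""

    rho: float
    p_value: float
    n_nodes: int
    degenerate: bool = False


def _centrality_pairs(net: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    cents = topology.centralities(net)
    nodes = sorted(cents)
    nd = np.array([cents[n].normalized_degree for n in nodes])
    bc = np.array([cents[n].betweenness for n in nodes])
    return nd, bc


def coupling(net: nx.Graph) -> CouplingResult:
    """Correlation between normalised degree and betweenness across nodes.

    Higher coupling indicates redundancy between hubs and gatekeepers: a
    network where high-betweenness bridges are also hubs has stand-in nodes
    to hold it together when a bridge is lost.
    """
    nd, bc = _centrality_pairs(net)
    if np.ptp(nd) == 0 or np.ptp(bc) == 0:
        return CouplingResult(rho=float("nan"), p_value=float("nan"),
                              n_nodes=len(nd), degenerate=True)
    rho, p = stats.spearmanr(nd, bc)
    return CouplingResult(rho=float(rho), p_value=float(p), n_nodes=len(nd))


def compare_coupling(net_a: nx.Graph, net_b: nx.Graph, B: int = 1000,
                     seed: int = 0) -> float:
    """Monte-Carlo (node bootstrap) two-sided p for ρ_A ≠ ρ_B.

    Nodes are resampled with replacement within each network B times; the
    bootstrap distribution of ρ*_A − ρ*_B is centred on its mean and the
    p-value is the fraction at least as extreme as the observed difference.
    """
    if net_a.number_of_nodes() < 10 or net_b.number_of_nodes() < 10:
        raise ValueError("coupling comparison needs at least 10 nodes per network")
    ca, cb = coupling(net_a), coupling(net_b)
    if ca.degenerate or cb.degenerate:
        raise ValueError("degenerate centralities; coupling undefined")
    d0 = ca.rho - cb.rho
    rng = np.random.default_rng(seed)
    pairs_a = _centrality_pairs(net_a)
    pairs_b = _centrality_pairs(net_b)
    diffs = np.empty(B)
    for b in range(B):
        rs = []
        for nd, bc in (pairs_a, pairs_b):
            idx = rng.integers(0, len(nd), size=len(nd))
            if np.ptp(nd[idx]) == 0 or np.ptp(bc[idx]) == 0:
                rs.append(0.0)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, _ = stats.spearmanr(nd[idx], bc[idx])
            rs.append(float(r) if np.isfinite(r) else 0.0)
        diffs[b] = rs[0] - rs[1]
    centered = diffs - diffs.mean()
    return float((1 + np.sum(np.abs(centered) >= abs(d0))) / (B + 1))
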