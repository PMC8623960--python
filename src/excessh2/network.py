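"""Hub-gene screening on a protein-interaction network.

Nodes are ranked by four topological methods — harmonic closeness, stress
centrality, edge-percolated component (EPC) and maximum neighborhood
component (MNC) — and hub genes are the intersection of the top quantile
(default 25%) of every ranking. A permutation test then asks whether the
hub subnetwork carries more internal edges than equal-sized random node
subsets.

Geodesic-based methods (closeness, stress) ignore edge confidences and
use unweighted shortest paths; EPC uses the confidences as independent
edge-retention probabilities. Harmonic closeness (sum of reciprocal
distances, with 1/inf = 0) is used so disconnected networks — routine for
PPI subnetworks — still get finite scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

METHODS = ("closeness", "stress", "epc", "mnc")


def _check(net: nx.Graph) -> None:
    if net.is_directed() or net.is_multigraph():
        raise ValueError("network must be a simple undirected graph")
    if any(u == v for u, v in net.edges):
        raise ValueError("network must have no self-loops")


def closeness(net: nx.Graph) -> dict[str, float]:
    """Harmonic closeness C(v) = Σ_{u≠v} 1/d(v,u) over unweighted
    shortest paths; unreachable pairs contribute 0."""
    _check(net)
    return {v: float(c) for v, c in nx.harmonic_centrality(net).items()}


def stress(net: nx.Graph) -> dict[str, int]:
    """Stress centrality: the number of shortest paths between unordered
    pairs (s, t), s ≠ t ≠ v, that pass through v, each path counted once.

    Uses BFS geodesic counts: σ_st(v) = σ_sv · σ_vt when
    d(s,v) + d(v,t) = d(s,t).
    """
    _check(net)
    nodes = list(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        i = idx[s]
        d, sig = _bfs_counts(net, s)
        for v, dv in d.items():
            dist[i, idx[v]] = dv
            sigma[i, idx[v]] = sig[v]
    out: dict[str, int] = {}
    for v in nodes:
        k = idx[v]
        through = dist[:, k][:, None] + dist[k, :][None, :]
        on_geo = np.isfinite(dist) & (through == dist)
        paths = sigma[:, k][:, None] * sigma[k, :][None, :]
        paths = np.where(on_geo, paths, 0.0)
        paths[k, :] = 0.0
        paths[:, k] = 0.0
        np.fill_diagonal(paths, 0.0)
        out[v] = int(round(paths.sum() / 2.0))  # unordered pairs
    return out


def _bfs_counts(net: nx.Graph, s) -> tuple[dict, dict]:
    """Distances and geodesic counts from s (Brandes' forward pass)."""
    d = {s: 0}
    sigma = {s: 1}
    queue = [s]
    while queue:
        nxt = []
        for u in queue:
            for w in net.neighbors(u):
                if w not in d:
                    d[w] = d[u] + 1
                    sigma[w] = 0
                    nxt.append(w)
                if d[w] == d[u] + 1:
                    sigma[w] += sigma[u]
        queue = nxt
    return d, sigma


def mnc(net: nx.Graph) -> dict[str, int]:
    """Maximum neighborhood component: size of the largest connected
    component of the subgraph induced by the open neighborhood of v
    (0 for isolated nodes)."""
    _check(net)
    out = {}
    for v in net.nodes:
        nbrs = list(net.neighbors(v))
        if not nbrs:
            out[v] = 0
            continue
        sub = net.subgraph(nbrs)
        out[v] = max(len(c) for c in nx.connected_components(sub))
    return out


def epc(
    net: nx.Graph,
    n_realizations: int = 1000,
    retention: dict | float | None = None,
    seed: int = 0,
) -> dict[str, float]:
    """Edge-percolated component: Monte-Carlo estimate of the expected
    number of nodes reachable from v (excluding v) when each edge is kept
    independently with its retention probability.

    Retention defaults to the edge ``confidence`` attribute, falling back
    to 0.5 for edges without one; a scalar applies to all edges.
    """
    _check(net)
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    edges = list(net.edges)
    if isinstance(retention, dict):
        probs = np.array([retention[e] if e in retention else retention[(e[1], e[0])] for e in edges])
    elif retention is not None:
        probs = np.full(len(edges), float(retention))
    else:
        probs = np.array(
            [net.edges[e].get("confidence", 0.5) for e in edges], dtype=float
        )
    rng = np.random.default_rng(seed)
    totals = {v: 0.0 for v in net.nodes}
    for _ in range(n_realizations):
        keep = rng.random(len(edges)) < probs
        sub = nx.Graph()
        sub.add_nodes_from(net.nodes)
        sub.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(sub):
            size = len(comp)
            for v in comp:
                totals[v] += size - 1
    return {v: t / n_realizations for v, t in totals.items()}


@dataclass
class CentralityTable:
    """Per-node scores for the four ranking methods."""

    scores: dict[str, dict[str, float]]  # method -> node -> score

    def __post_init__(self) -> None:
        missing = set(METHODS) - set(self.scores)
        if missing:
            raise ValueError(f"missing methods: {sorted(missing)}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.scores[METHODS[0]])


def score_nodes(
    net: nx.Graph, epc_realizations: int = 1000, seed: int = 0
) -> CentralityTable:
    """All four centralities for every node."""
    return CentralityTable(
        scores={
            "closeness": closeness(net),
            "stress": {v: float(s) for v, s in stress(net).items()},
            "epc": epc(net, n_realizations=epc_realizations, seed=seed),
            "mnc": {v: float(s) for v, s in mnc(net).items()},
        }
    )


@dataclass
class HubSet:
    members: frozenset[str]
    quantile: float
    cutoffs: dict[str, float]  # per-method score at the quantile rank


def hub_genes(scores: CentralityTable, quantile: float = 0.25) -> HubSet:
    """Shared top quantile across all four rankings.

    Per method the cutoff is the score of the ceil(quantile·n)-th ranked
    node (descending); ties at the cutoff are included. The hub set is the
    intersection of the four top groups and may be empty.
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError("quantile must lie in (0, 1]")
    nodes = scores.nodes
    k = math.ceil(quantile * len(nodes))
    cutoffs: dict[str, float] = {}
    tops: list[set[str]] = []
    for method in METHODS:
        sc = scores.scores[method]
        ranked = sorted(nodes, key=lambda v: (-sc[v], v))
        cutoff = sc[ranked[k - 1]]
        cutoffs[method] = cutoff
        tops.append({v for v in nodes if sc[v] >= cutoff})
    members = frozenset(set.intersection(*tops))
    if not members:
        logger.info("hub set is empty at quantile %.2f", quantile)
    return HubSet(members=members, quantile=quantile, cutoffs=cutoffs)


def subnetwork_enrichment_p(
    net: nx.Graph, subset: list[str], n_perm: int = 1000, seed: int = 0
) -> float:
    """Permutation p-value for the internal edge count of ``subset``
    against equal-size uniform random node subsets:
    p = (1 + #{perm >= observed}) / (1 + n_perm)."""
    _check(net)
    subset = list(subset)
    missing = set(subset) - set(net.nodes)
    if missing:
        raise ValueError(f"subset nodes not in network: {sorted(missing)[:5]}")
    if len(subset) < 2:
        raise ValueError("subset must have at least 2 nodes")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    observed = net.subgraph(subset).number_of_edges()
    nodes = np.array(sorted(net.nodes))
    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        draw = rng.choice(nodes, size=len(subset), replace=False)
        if net.subgraph(draw).number_of_edges() >= observed:
            ge += 1
    return (1.0 + ge) / (1.0 + n_perm)
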