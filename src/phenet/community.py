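"""Resolution-parameterized modularity and Louvain community detection.

Modularity of a partition of a weighted undirected graph, with resolution γ
multiplying the configuration-model null term (Reichardt–Bornholdt):

    Q(γ) = (1/2m) Σ_ij [ A_ij − γ k_i k_j / (2m) ] δ(c_i, c_j)

with k_i the weighted degree and m the total edge weight.  γ = 1 recovers
Newman–Girvan modularity; larger γ favors more, smaller communities.

The Louvain algorithm greedily maximizes Q in two alternating phases: local
single-node moves (each node to the neighboring community with the largest
positive gain), then aggregation of communities into super-nodes whose
self-loops carry the intra-community weight.  The optimization is heuristic
and order-dependent; here the node sweep order is a seeded shuffle re-drawn
each phase, so a fixed (graph, γ, seed) is exactly reproducible.

An exhaustive Bell-number enumeration over all set partitions serves as the
exact oracle for graphs of at most 10 nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .graphs import UnipartiteGraphBuilder, validate_graph

logger = logging.getLogger(__name__)

_GAIN_TOL = 1e-12  # a move must beat the incumbent by more than this


@dataclass
class Partition:
    """Node→community assignment with its modularity at resolution γ.

    ``phase_q`` records modularity after each completed Louvain level
    (monotone non-decreasing); empty for partitions not produced by Louvain.
    """

    assignment: dict[Hashable, int]
    q: float
    gamma: float = 1.0
    seed: int | None = None
    phase_q: list[float] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, set()).add(n)
        return out

    def sizes(self) -> dict[int, int]:
        return {c: len(members) for c, members in self.communities().items()}


def _graph_arrays(G: nx.Graph):
    m = G.size(weight="weight")
    if m <= 0:
        raise ValueError("modularity is undefined for a graph with no edge weight")
    deg = dict(G.degree(weight="weight"))  # self-loops count twice
    return m, deg


def modularity(
    G: nx.Graph,
    partition: Partition | Mapping[Hashable, int],
    gamma: float = 1.0,
) -> float:
    """Q(γ) of a partition; invariant under relabeling of community ids."""
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    missing = set(G.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(map(str, missing))[:5]}")
    m, deg = _graph_arrays(G)
    intra: dict[int, float] = {}
    dtot: dict[int, float] = {}
    for n in G:
        c = assignment[n]
        dtot[c] = dtot.get(c, 0.0) + deg[n]
    for u, v, data in G.edges(data=True):
        if assignment[u] == assignment[v]:
            c = assignment[u]
            intra[c] = intra.get(c, 0.0) + data.get("weight", 1.0)
    q = 0.0
    for c, d in dtot.items():
        q += intra.get(c, 0.0) / m - gamma * (d / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain


def _one_level(
    adj: dict, deg: dict, m: float, gamma: float, rng: np.random.Generator
) -> tuple[dict, bool]:
    """Phase 1: local moves until no single move improves Q.

    ``adj`` maps node → {neighbor: weight} (self-loops excluded; they never
    change under a move).  Ties break toward the incumbent community, then the
    lowest community id.  Returns (node→community, any_move_happened).
    """
    nodes = list(adj)
    node2com = {n: i for i, n in enumerate(nodes)}
    sigma_tot = {node2com[n]: deg[n] for n in nodes}
    two_m = 2.0 * m
    moved_any = False
    improved = True
    while improved:
        improved = False
        order = list(nodes)
        rng.shuffle(order)
        for n in order:
            com = node2com[n]
            k_n = deg[n]
            # weight from n to each neighboring community
            w_to: dict[int, float] = {}
            for nbr, w in adj[n].items():
                w_to[node2com[nbr]] = w_to.get(node2com[nbr], 0.0) + w
            sigma_tot[com] -= k_n
            base = w_to.get(com, 0.0) - gamma * k_n * sigma_tot[com] / two_m
            best_com, best_gain = com, base
            for cand in sorted(w_to):
                if cand == com:
                    continue
                gain = w_to[cand] - gamma * k_n * sigma_tot[cand] / two_m
                if gain > best_gain + _GAIN_TOL:
                    best_com, best_gain = cand, gain
            sigma_tot[best_com] = sigma_tot.get(best_com, 0.0) + k_n
            if best_com != com:
                node2com[n] = best_com
                improved = True
                moved_any = True
                if sigma_tot[com] == 0:
                    del sigma_tot[com]
    return node2com, moved_any


def _aggregate(G: nx.Graph, node2com: dict) -> nx.Graph:
    """Phase 2: communities become super-nodes; self-loops carry intra weight."""
    H = nx.Graph()
    H.add_nodes_from(set(node2com.values()))
    for u, v, data in G.edges(data=True):
        cu, cv = node2com[u], node2com[v]
        w = data.get("weight", 1.0)
        if H.has_edge(cu, cv):
            H[cu][cv]["weight"] += w
        else:
            H.add_edge(cu, cv, weight=w)
    return H


def louvain(G: nx.Graph, gamma: float = 1.0, seed: int | None = None) -> Partition:
    """Greedy modularity optimization; deterministic for fixed (graph, γ, seed).

    Bipartite graphs are partitioned as plain weighted graphs (subject and
    feature nodes may share a community).
    """
    m, _ = _graph_arrays(G)
    rng = np.random.default_rng(seed)
    # flat assignment from original node to current community
    flat = {n: n for n in G.nodes}
    current = G
    phase_q: list[float] = []
    while True:
        m_cur = current.size(weight="weight")
        deg = dict(current.degree(weight="weight"))
        adj = {
            n: {nbr: d.get("weight", 1.0) for nbr, d in current[n].items() if nbr != n}
            for n in current
        }
        node2com, moved = _one_level(adj, deg, m_cur, gamma, rng)
        flat = {n: node2com[flat[n]] for n in flat}
        phase_q.append(modularity(G, flat, gamma))
        if not moved:
            break
        current = _aggregate(current, node2com)
    # relabel communities compactly in order of first appearance
    relabel: dict[int, int] = {}
    assignment: dict[Hashable, int] = {}
    for n in G.nodes:
        c = flat[n]
        if c not in relabel:
            relabel[c] = len(relabel)
        assignment[n] = relabel[c]
    q = modularity(G, assignment, gamma)
    return Partition(assignment=assignment, q=q, gamma=gamma, seed=seed, phase_q=phase_q)


# ---------------------------------------------------------------------------
# Exhaustive oracle

MAX_BRUTE_FORCE_NODES = 10


def _set_partitions(n: int) -> Iterator[list[int]]:
    """All set partitions of range(n) as restricted-growth label strings."""
    labels = [0] * n
    maxes = [0] * n

    def rec(i: int) -> Iterator[list[int]]:
        if i == n:
            yield labels.copy()
            return
        top = maxes[i - 1] if i > 0 else -1
        for lab in range(top + 2):
            labels[i] = lab
            maxes[i] = max(top, lab)
            yield from rec(i + 1)

    return rec(0)


def brute_force_best_partition(G: nx.Graph, gamma: float = 1.0) -> Partition:
    """Exact maximum-modularity partition by enumerating all set partitions.

    Refuses graphs with more than 10 nodes (Bell(10) = 115 975 partitions).
    Ties break toward fewer communities, then the lexicographically smallest
    canonical label string.
    """
    nodes = list(G.nodes)
    n = len(nodes)
    if n > MAX_BRUTE_FORCE_NODES:
        raise ValueError(f"exhaustive search limited to {MAX_BRUTE_FORCE_NODES} nodes, got {n}")
    m, deg = _graph_arrays(G)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    k = np.array([deg[x] for x in nodes], dtype=float)
    B = A - gamma * np.outer(k, k) / (2.0 * m)
    best_q = -np.inf
    best: list[int] | None = None
    for labels in _set_partitions(n):
        lab = np.asarray(labels)
        same = lab[:, None] == lab[None, :]
        q = B[same].sum() / (2.0 * m)
        if q > best_q + 1e-15 or (
            abs(q - best_q) <= 1e-15
            and best is not None
            and (max(labels) < max(best) or (max(labels) == max(best) and labels < best))
        ):
            best_q, best = q, labels.copy()
    assert best is not None
    assignment = {nodes[i]: best[i] for i in range(n)}
    return Partition(assignment=assignment, q=float(best_q), gamma=gamma, seed=None)


# ---------------------------------------------------------------------------
# Singleton handling


def drop_singleton_communities(
    partition: Partition, G: nx.Graph
) -> tuple[Partition, list]:
    """Remove nodes that form communities of one; relabel survivors 1..K by size.

    Mirrors the post-hoc exclusion of subjects that partition into one-node
    communities.  Community ids in the returned partition run 1..K in
    descending size order (ties by smallest member id as string, for stable
    numbering across runs).  The returned Q is recomputed on the subgraph
    induced by the retained nodes.
    """
    coms = partition.communities()
    removed = sorted(
        (next(iter(mem)) for mem in coms.values() if len(mem) == 1), key=str
    )
    keep = {c: mem for c, mem in coms.items() if len(mem) > 1}
    if not keep:
        raise ValueError("every community is a singleton; nothing left to analyze")
    if removed:
        logger.info("dropping %d singleton node(s): %s", len(removed), removed)
    ordered = sorted(
        keep.items(), key=lambda cm: (-len(cm[1]), min(map(str, cm[1])))
    )
    assignment = {n: new_id for new_id, (_, mem) in enumerate(ordered, 1) for n in mem}
    sub = G.subgraph(assignment)
    q = modularity(sub, assignment, partition.gamma) if sub.size(weight="weight") > 0 else float("nan")
    new = Partition(
        assignment=assignment,
        q=q,
        gamma=partition.gamma,
        seed=partition.seed,
        phase_q=list(partition.phase_q),
    )
    return new, removed


# ---------------------------------------------------------------------------
# Estimator facade


class LouvainCommunities(BaseEstimator, ClusterMixin):
    """Community detection over a precomputed subject distance matrix.

    A scikit-learn clusterer: ``fit(D)`` thresholds the distance matrix into a
    similarity graph (edge iff d ≤ ``threshold``, weight 1 − d) and partitions
    it by Louvain at the given resolution.  Composes with
    :class:`~phenet.features.PairwiseDistances` in a sklearn ``Pipeline``.

    Parameters
    ----------
    threshold : float, default 0.4
        Cosine-distance cutoff for edges.
    resolution : float, default 1.0
        γ multiplying modularity's null term; larger values favor more,
        smaller communities.
    random_state : int or None
        Seed for the node sweep order.
    drop_singletons : bool, default True
        Exclude one-node communities from the reported labels (marked −1,
        the sklearn noise convention).

    Attributes
    ----------
    labels_ : ndarray of int
        Community label per subject; −1 for dropped singletons.
    partition_ : Partition
        Full partition (before singleton dropping).
    modularity_ : float
        Q of the full partition at ``resolution``.
    graph_ : networkx.Graph
        The thresholded similarity graph.
    """

    def __init__(
        self,
        threshold: float = 0.4,
        resolution: float = 1.0,
        random_state: int | None = None,
        drop_singletons: bool = True,
    ):
        self.threshold = threshold
        self.resolution = resolution
        self.random_state = random_state
        self.drop_singletons = drop_singletons

    def fit(self, X, y=None) -> "LouvainCommunities":
        D = pd.DataFrame(X)
        if not isinstance(X, pd.DataFrame):
            D.index = D.columns = [str(i) for i in range(len(D))]
        self.graph_ = UnipartiteGraphBuilder(self.threshold).fit().transform(D)
        validate_graph(self.graph_)
        self.partition_ = louvain(self.graph_, gamma=self.resolution, seed=self.random_state)
        self.modularity_ = self.partition_.q
        assignment = self.partition_.assignment
        if self.drop_singletons:
            kept, self.dropped_ = drop_singleton_communities(self.partition_, self.graph_)
            self.kept_partition_ = kept
            labels = {n: kept.assignment.get(n, -1) for n in assignment}
        else:
            self.dropped_ = []
            self.kept_partition_ = self.partition_
            labels = assignment
        self.labels_ = np.array([labels[str(s)] for s in D.index])
        return self
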