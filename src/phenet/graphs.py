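"""Phenotype graph construction and GraphML/GEXF round-tripping.

Two weighted undirected graphs are built from a cohort's normalized feature
matrix:

* a **bipartite** subject–feature graph, where an edge joins subject *s* to
  superclass *c* with weight equal to the normalized feature score (zero cells
  produce no edge — a zero-weight edge is indistinguishable from no edge in
  weighted modularity);
* a **unipartite** subject–subject graph, where an edge joins two subjects whose
  cosine distance is at or below a threshold (0.4 by default), weighted by the
  similarity ``1 − d`` so that larger weight means more alike.

Node kinds (``subject``/``feature``) and the graph mode travel as attributes so
files re-imported from disk revalidate structurally.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

SUBJECT = "subject"
FEATURE = "feature"


class GraphValidationError(ValueError):
    """A graph violates a structural invariant (bipartiteness, weights, loops)."""


def validate_graph(G: nx.Graph) -> None:
    """Enforce the structural invariants: positive weights, no self-loops,
    and — for bipartite mode — no subject–subject or feature–feature edges."""
    mode = G.graph.get("mode", "unipartite")
    for u, v, data in G.edges(data=True):
        w = data.get("weight")
        if w is None or w <= 0:
            raise GraphValidationError(f"edge ({u!r}, {v!r}) has non-positive weight {w!r}")
        if u == v:
            raise GraphValidationError(f"self-loop at node {u!r}")
    if mode == "bipartite":
        for u, v in G.edges():
            ku, kv = G.nodes[u].get("kind"), G.nodes[v].get("kind")
            if {ku, kv} != {SUBJECT, FEATURE}:
                raise GraphValidationError(
                    f"bipartite violation: edge ({u!r}[{ku}], {v!r}[{kv}])"
                )
    else:
        kinds = {G.nodes[n].get("kind", SUBJECT) for n in G}
        if kinds - {SUBJECT}:
            raise GraphValidationError(f"unipartite graph contains non-subject nodes: {kinds}")


class BipartiteGraphBuilder(BaseEstimator, TransformerMixin):
    """Subject–feature graph from a normalized feature matrix."""

    def fit(self, X=None, y=None) -> "BipartiteGraphBuilder":
        return self

    def transform(self, X: pd.DataFrame) -> nx.Graph:
        X = pd.DataFrame(X)
        if X.empty:
            raise ValueError("feature matrix is empty")
        subjects = [str(s) for s in X.index]
        features = [str(c) for c in X.columns]
        clash = set(subjects) & set(features)
        if clash:
            raise ValueError(f"subject ids collide with feature names: {sorted(clash)}")
        G = nx.Graph(mode="bipartite")
        G.add_nodes_from(subjects, kind=SUBJECT)
        G.add_nodes_from(features, kind=FEATURE)
        for s, row in zip(subjects, X.values):
            for c, w in zip(features, row):
                if w > 0:
                    G.add_edge(s, c, weight=float(w))
        for s in subjects:
            if G.degree(s) == 0:
                logger.warning("subject %r has an all-zero feature row (isolated node)", s)
        validate_graph(G)
        return G


class UnipartiteGraphBuilder(BaseEstimator, TransformerMixin):
    """Thresholded subject–subject similarity graph from a distance matrix.

    Edge (i, j) exists iff d(i, j) ≤ ``threshold`` (inclusive), with weight
    1 − d(i, j).  Isolated subjects are retained — they surface downstream as
    singleton communities rather than being silently pre-filtered.
    """

    def __init__(self, threshold: float = 0.4):
        self.threshold = threshold

    def fit(self, X=None, y=None) -> "UnipartiteGraphBuilder":
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        return self

    def transform(self, X: pd.DataFrame) -> nx.Graph:
        self.fit()
        D = pd.DataFrame(X)
        subjects = [str(s) for s in D.index]
        G = nx.Graph(mode="unipartite", threshold=float(self.threshold))
        G.add_nodes_from(subjects, kind=SUBJECT)
        d = D.values
        n = len(subjects)
        for i in range(n):
            for j in range(i + 1, n):
                dij = float(d[i, j])
                if dij <= self.threshold:
                    if dij == self.threshold:
                        logger.debug(
                            "boundary edge (%s, %s): d == threshold %.6g kept",
                            subjects[i], subjects[j], self.threshold,
                        )
                    G.add_edge(subjects[i], subjects[j], weight=1.0 - dij)
        isolated = [n_ for n_ in G if G.degree(n_) == 0]
        if isolated:
            logger.info("%d isolated subject(s) at threshold %.3g: %s",
                        len(isolated), self.threshold, isolated)
        validate_graph(G)
        return G


def build_bipartite(features: pd.DataFrame) -> nx.Graph:
    """Functional wrapper over :class:`BipartiteGraphBuilder`."""
    return BipartiteGraphBuilder().fit().transform(features)


def build_unipartite(distances: pd.DataFrame, threshold: float = 0.4) -> nx.Graph:
    """Functional wrapper over :class:`UnipartiteGraphBuilder`."""
    return UnipartiteGraphBuilder(threshold).fit().transform(distances)


def node_degrees(G: nx.Graph) -> dict[str, tuple[int, float]]:
    """Per node: (degree, weighted degree).

    Handshake identities hold: Σ degree = 2·|E| and Σ weighted degree = 2m.
    """
    wdeg = dict(G.degree(weight="weight"))
    return {n: (G.degree(n), float(wdeg[n])) for n in G}


def write_graph(G: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write GraphML or GEXF (inferred from the suffix when ``fmt`` is None)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    validate_graph(G)
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "gexf":
        # GEXF does not carry graph-level attributes; stash mode on each node.
        H = G.copy()
        for n in H:
            H.nodes[n]["graph_mode"] = G.graph.get("mode", "unipartite")
        nx.write_gexf(H, path)
    else:
        raise ValueError(f"unsupported graph format {fmt!r} (use graphml or gexf)")


def read_graph(path: str | Path, fmt: str | None = None) -> nx.Graph:
    """Read GraphML/GEXF written by :func:`write_graph` and revalidate it."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    try:
        if fmt == "graphml":
            G = nx.read_graphml(path)
        elif fmt == "gexf":
            G = nx.read_gexf(path)
        else:
            raise ValueError(f"unsupported graph format {fmt!r} (use graphml or gexf)")
    except ValueError:
        raise
    except Exception as exc:  # lxml/expat errors carry line context in str(exc)
        raise GraphValidationError(f"cannot parse {path}: {exc}") from exc
    G = nx.Graph(G)  # drop any multi/directed wrapper
    modes = {d.pop("graph_mode") for _, d in G.nodes(data=True) if "graph_mode" in d}
    if G.graph.get("mode") not in ("bipartite", "unipartite"):
        # GEXF hijacks graph["mode"] for its static/dynamic flag
        if modes:
            G.graph["mode"] = modes.pop()
        else:
            kinds = {G.nodes[n].get("kind", SUBJECT) for n in G}
            G.graph["mode"] = "bipartite" if FEATURE in kinds else "unipartite"
    for n in G:
        G.nodes[n].setdefault("kind", SUBJECT)
    validate_graph(G)
    return G
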