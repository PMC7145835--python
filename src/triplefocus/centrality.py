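"""Normalized degree and shortest-path betweenness centrality.

Degree centrality is the node degree divided by ``n - 1``, the maximum
possible degree in a simple graph of ``n`` nodes. Betweenness centrality of
a node v sums, over all unordered pairs {s, t} (s != v != t), the fraction
of shortest s-t paths (geodesics) that pass through v; the fast path is
Brandes' dependency-accumulation algorithm, computed on the unweighted,
undirected graph. Normalization divides by the number of pairs a node could
intermediate, ``(n - 1)(n - 2) / 2``, so values land in [0, 1].

Conventions, stated because they matter for cross-tool comparison:

* ``n`` is the full node count of the analyzed graph, isolated nodes
  included, for both normalizations.
* Disconnected graphs sum over reachable pairs only; there is no
  per-component rescaling.
* Graphs with n < 3 have betweenness 0 everywhere; n < 2 degree 0.

A brute-force geodesic-enumeration oracle (:func:`betweenness_oracle`)
backs the property tests; it is deliberately independent of the Brandes
path.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

from .graph import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "CentralityTable",
    "degree_centrality",
    "betweenness_centrality",
    "betweenness_oracle",
    "centrality_table",
    "rank_nodes",
]

ORACLE_MAX_NODES = 15


@dataclass(frozen=True)
class CentralityTable:
    """Per-node normalized degree (C_D) and betweenness (C_B) values."""

    degree: dict[str, float]
    betweenness: dict[str, float]

    @property
    def nodes(self) -> set[str]:
        return set(self.degree)

    def row(self, node: str) -> tuple[float, float]:
        return self.degree[node], self.betweenness[node]

    def to_frame(self):
        """As a DataFrame sorted by betweenness desc, symbol asc."""
        import pandas as pd

        df = pd.DataFrame(
            {
                "gene": sorted(self.degree),
            }
        )
        df["degree_centrality"] = df["gene"].map(self.degree)
        df["betweenness_centrality"] = df["gene"].map(self.betweenness)
        return df.sort_values(
            ["betweenness_centrality", "gene"], ascending=[False, True]
        ).reset_index(drop=True)


def degree_centrality(g: Graph) -> dict[str, float]:
    """deg(v) / (n-1) per node; all zeros (with a warning) for n < 2."""
    n = g.n
    if n < 2:
        if n:
            logger.warning("degree_centrality: n=%d < 2, reporting zeros", n)
        return {v: 0.0 for v in g.adjacency}
    return {v: len(nbrs) / (n - 1) for v, nbrs in g.adjacency.items()}


def betweenness_centrality(g: Graph) -> dict[str, float]:
    """Normalized betweenness via Brandes' algorithm (unweighted BFS).

    For each source s a BFS builds the shortest-path DAG with path counts
    sigma, then dependencies delta are accumulated back from the leaves:
    delta[v] += sigma[v]/sigma[w] * (1 + delta[w]) over successors w. The
    per-source accumulation counts each unordered pair twice on an
    undirected graph, and normalization by (n-1)(n-2)/2 pairs folds the
    half into a single division by (n-1)(n-2).
    """
    nodes = sorted(g.adjacency)
    n = len(nodes)
    raw = dict.fromkeys(nodes, 0.0)
    if n < 3:
        return raw
    for s in nodes:
        order: list[str] = []
        pred: dict[str, list[str]] = {v: [] for v in nodes}
        sigma = dict.fromkeys(nodes, 0.0)
        sigma[s] = 1.0
        dist = dict.fromkeys(nodes, -1)
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g.adjacency[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        delta = dict.fromkeys(nodes, 0.0)
        while order:
            w = order.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                raw[w] += delta[w]
    scale = 1.0 / ((n - 1) * (n - 2))
    return {v: b * scale for v, b in raw.items()}


def betweenness_oracle(g: Graph) -> dict[str, float]:
    """Betweenness by explicit enumeration of every geodesic.

    For each unordered pair {s, t}: BFS from s, walk the predecessor DAG to
    list all shortest s-t paths, and credit each interior node with
    (paths through it) / (total paths). Exponential in the worst case, so
    refuses graphs with more than 15 nodes. Same normalization contract as
    :func:`betweenness_centrality`.
    """
    nodes = sorted(g.adjacency)
    n = len(nodes)
    if n > ORACLE_MAX_NODES:
        raise ValueError(
            f"betweenness_oracle caps at {ORACLE_MAX_NODES} nodes, got {n}"
        )
    raw = dict.fromkeys(nodes, 0.0)
    if n < 3:
        return raw
    for i, s in enumerate(nodes):
        dist, pred = _bfs_dag(g, s)
        for t in nodes[i + 1 :]:
            if dist[t] < 0:
                continue
            paths = _all_paths(pred, s, t)
            if not paths:
                continue
            through: dict[str, int] = {}
            for p in paths:
                for v in p[1:-1]:
                    through[v] = through.get(v, 0) + 1
            for v, c in through.items():
                raw[v] += c / len(paths)
    scale = 2.0 / ((n - 1) * (n - 2))
    return {v: b * scale for v, b in raw.items()}


def _bfs_dag(g: Graph, s: str) -> tuple[dict[str, int], dict[str, list[str]]]:
    dist = dict.fromkeys(g.adjacency, -1)
    pred: dict[str, list[str]] = {v: [] for v in g.adjacency}
    dist[s] = 0
    queue = deque([s])
    while queue:
        v = queue.popleft()
        for w in g.adjacency[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
            if dist[w] == dist[v] + 1:
                pred[w].append(v)
    return dist, pred


def _all_paths(pred: dict[str, list[str]], s: str, t: str) -> list[list[str]]:
    """All geodesics s->t, rebuilt backwards through the predecessor DAG."""
    if t == s:
        return [[s]]
    out = []
    for p in pred[t]:
        for partial in _all_paths(pred, s, p):
            out.append(partial + [t])
    return out


def centrality_table(g: Graph) -> CentralityTable:
    """Both centralities for every node of ``g``."""
    return CentralityTable(
        degree=degree_centrality(g), betweenness=betweenness_centrality(g)
    )


def rank_nodes(
    table: CentralityTable, by: str = "betweenness", top_k: int | None = None
) -> list[str]:
    """Nodes sorted descending by the chosen centrality.

    Ties break lexicographically by symbol, making the ranking
    deterministic. ``top_k`` <= 0 returns an empty list; ``None`` returns
    all nodes.
    """
    if by not in ("betweenness", "degree"):
        raise ValueError(f"unknown centrality {by!r}")
    if not table.degree:
        raise ValueError("rank_nodes: empty centrality table")
    values = table.betweenness if by == "betweenness" else table.degree
    ranked = sorted(values, key=lambda v: (-values[v], v))
    if top_k is None:
        return ranked
    if top_k <= 0:
        return []
    return ranked[:top_k]
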