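"""Simple undirected graphs over gene symbols.

The pipeline treats protein-protein interactions as unweighted, undirected
edges once the confidence filter has been applied; a minimal adjacency-set
graph is all the downstream centrality and community code needs. Disease
networks are *induced subgraphs* on a seed gene list: every seed symbol is a
node even if it has no surviving interaction, so node counts equal gene-list
sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io import GeneSet, InteractionRecord

__all__ = [
    "Graph",
    "NetworkSummary",
    "build_graph",
    "union_graphs",
    "node_overlap",
    "summarize",
    "connected_components",
    "truncate_sig",
]


@dataclass
class Graph:
    """Simple undirected graph: symmetric adjacency sets, no self-loops."""

    adjacency: dict[str, set[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.adjacency)

    @property
    def n(self) -> int:
        return len(self.adjacency)

    @property
    def m(self) -> int:
        return sum(len(nbrs) for nbrs in self.adjacency.values()) // 2

    def add_node(self, v: str) -> None:
        self.adjacency.setdefault(v, set())

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            raise ValueError(f"self-loop not allowed: {u}")
        self.add_node(u)
        self.add_node(v)
        self.adjacency[u].add(v)
        self.adjacency[v].add(u)

    def has_edge(self, u: str, v: str) -> bool:
        return v in self.adjacency.get(u, ())

    def degree(self, v: str) -> int:
        return len(self.adjacency[v])

    def neighbors(self, v: str) -> set[str]:
        return self.adjacency[v]

    def edges(self) -> list[tuple[str, str]]:
        """All edges as canonical sorted pairs, lexicographic order."""
        out = [
            (u, v)
            for u, nbrs in self.adjacency.items()
            for v in nbrs
            if u < v
        ]
        out.sort()
        return out

    def subgraph(self, keep: Iterable[str]) -> "Graph":
        keep = set(keep)
        g = Graph()
        for v in self.adjacency.keys() & keep:
            g.adjacency[v] = self.adjacency[v] & keep
        return g

    def copy(self) -> "Graph":
        g = Graph()
        g.adjacency = {v: set(nbrs) for v, nbrs in self.adjacency.items()}
        return g


@dataclass(frozen=True)
class NetworkSummary:
    """One summary row: size plus mean normalized centralities."""

    name: str
    n: int
    m: int
    mean_degree_centrality: float
    mean_betweenness_centrality: float

    def truncated(self, sig: int = 3) -> "NetworkSummary":
        """Reporting variant with means truncated toward zero at ``sig``
        significant figures, the convention used in published network
        characteristic tables."""
        return NetworkSummary(
            self.name,
            self.n,
            self.m,
            truncate_sig(self.mean_degree_centrality, sig),
            truncate_sig(self.mean_betweenness_centrality, sig),
        )


def truncate_sig(x: float, sig: int = 3) -> float:
    """Truncate ``x`` toward zero at ``sig`` significant figures.

    0.011955 -> 0.0119 and 0.10699 -> 0.106 at sig=3; note these differ
    from round-half-even results, which is why truncation is its own mode.
    """
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (sig - 1 - exponent)
    # nudge by one part in 1e12 so values stored as 0.10599999... truncate
    # to their intended decimal, not one ulp short
    return math.trunc(x * scale * (1 + 1e-12)) / scale


def build_graph(
    records: Sequence[InteractionRecord],
    seed_nodes: GeneSet | Iterable[str] | None = None,
) -> Graph:
    """Build a graph from filtered interaction records.

    With ``seed_nodes`` given, returns the induced subgraph on the seed
    set: only edges with *both* endpoints in the seeds are kept, and every
    seed appears as a node even when isolated. Without seeds, nodes are
    exactly the record endpoints.
    """
    g = Graph()
    if seed_nodes is None:
        for rec in records:
            g.add_edge(rec.node_a, rec.node_b)
        return g
    seeds = set(seed_nodes.members if isinstance(seed_nodes, GeneSet) else seed_nodes)
    for s in seeds:
        g.add_node(s)
    for rec in records:
        if rec.node_a in seeds and rec.node_b in seeds:
            g.add_edge(rec.node_a, rec.node_b)
    return g


def union_graphs(g1: Graph, g2: Graph) -> Graph:
    """Union of node sets and edge sets; commutative and idempotent."""
    g = g1.copy()
    for v, nbrs in g2.adjacency.items():
        g.adjacency.setdefault(v, set()).update(nbrs)
    return g


def node_overlap(*collections: Graph | GeneSet | Iterable[str]) -> list[str]:
    """Intersection of >=2 node/symbol collections, sorted lexicographically."""
    if len(collections) < 2:
        raise ValueError("node_overlap needs at least two collections")
    sets = []
    for coll in collections:
        if isinstance(coll, Graph):
            sets.append(coll.nodes)
        elif isinstance(coll, GeneSet):
            sets.append(set(coll.members))
        else:
            sets.append(set(coll))
    out = set.intersection(*sets)
    return sorted(out)


def connected_components(g: Graph) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member)."""
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in sorted(g.adjacency):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        while frontier:
            v = frontier.pop()
            for w in g.adjacency[v]:
                if w not in comp:
                    comp.add(w)
                    frontier.append(w)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def summarize(g: Graph, name: str) -> NetworkSummary:
    """Network summary row: n, m, and mean normalized centralities.

    The mean degree centrality of a simple graph is identically
    ``2m / (n(n-1))``; it is still computed by averaging the per-node table
    so the closed form doubles as a cross-check in tests. Graphs with fewer
    than two nodes report zero means.
    """
    from .centrality import betweenness_centrality, degree_centrality

    if g.n < 2:
        return NetworkSummary(name, g.n, g.m, 0.0, 0.0)
    deg = degree_centrality(g)
    btw = betweenness_centrality(g)
    mean_deg = sum(deg.values()) / g.n
    mean_btw = sum(btw.values()) / g.n
    return NetworkSummary(name, g.n, g.m, mean_deg, mean_btw)
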