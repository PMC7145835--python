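"""Community detection by greedy modularity maximization.

Modularity of a partition is

    Q = sum_c [ L_c / m  -  (D_c / 2m)^2 ]

with L_c the number of edges inside community c, D_c the total degree of
its members and m the edge count of the graph. The agglomerative greedy
(Clauset-Newman-Moore style) maximizer starts with every node in its own
community and repeatedly merges the pair of communities that most increases
Q, stopping when no merge has a positive gain. Merging communities i and j
changes Q by

    dQ(i, j) = L_ij / m  -  D_i D_j / (2 m^2)

where L_ij counts edges between them, so only connected pairs can ever
improve Q and the scan is restricted to them.

Tie-breaking is deterministic: a community is labelled by its
lexicographically smallest member, and among equal-gain pairs the pair
whose (smaller, larger) label tuple sorts first is merged. Isolated nodes
have dQ <= 0 against everything and stay singletons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import Graph

logger = logging.getLogger(__name__)

__all__ = [
    "Partition",
    "modularity",
    "greedy_modularity_communities",
    "filter_communities",
]


@dataclass
class Partition:
    """A node partition with its modularity score.

    Communities are stored largest-first (ties by smallest member symbol)
    and community ids are their positions in that order, so ids are stable
    for a given graph regardless of input ordering.
    """

    communities: list[set[str]]
    q: float
    merge_log: list[tuple[str, str, float, float]] = field(default_factory=list)

    @property
    def community_of(self) -> dict[str, int]:
        return {
            v: i for i, comm in enumerate(self.communities) for v in comm
        }

    def __len__(self) -> int:
        return len(self.communities)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.communities]

    def labels_for(self, nodes: list[str]) -> list[int]:
        """Community ids in the order of ``nodes`` (for external scoring)."""
        cof = self.community_of
        return [cof[v] for v in nodes]


def _sorted_communities(communities: list[set[str]]) -> list[set[str]]:
    return sorted(communities, key=lambda c: (-len(c), min(c)))


def modularity(g: Graph, communities: list[set[str]] | Partition) -> float:
    """Newman-Girvan modularity Q of a covering partition.

    Raises if the communities do not partition exactly the graph's node set
    or if the graph has no edges (Q is undefined at m = 0).
    """
    if isinstance(communities, Partition):
        communities = communities.communities
    m = g.m
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    covered: set[str] = set()
    for comm in communities:
        if covered & comm:
            raise ValueError("communities are not disjoint")
        covered |= comm
    if covered != g.nodes:
        raise ValueError("communities do not cover exactly the graph's nodes")
    q = 0.0
    for comm in communities:
        l_c = sum(
            1 for v in comm for w in g.adjacency[v] if w in comm and v < w
        )
        d_c = sum(len(g.adjacency[v]) for v in comm)
        q += l_c / m - (d_c / (2.0 * m)) ** 2
    return q


def greedy_modularity_communities(g: Graph) -> Partition:
    """Agglomerative greedy modularity maximization.

    Starts from singletons and merges the connected community pair with the
    largest strictly positive modularity gain until none remains. Every
    merge is appended to ``merge_log`` as (label_i, label_j, dQ, Q_after),
    so tests can assert that gains were strictly positive throughout.
    """
    if g.n == 0:
        return Partition(communities=[], q=0.0)
    m = g.m
    if m == 0:
        # no edges: all singletons, Q undefined; report 0 by convention
        comms = _sorted_communities([{v} for v in g.adjacency])
        return Partition(communities=comms, q=0.0)

    # community state keyed by label = smallest member symbol
    members: dict[str, set[str]] = {v: {v} for v in g.adjacency}
    degsum: dict[str, float] = {v: float(len(g.adjacency[v])) for v in g.adjacency}
    # between-community edge counts, symmetric dict-of-dicts
    between: dict[str, dict[str, float]] = {v: {} for v in g.adjacency}
    for u, v in g.edges():
        between[u][v] = between[u].get(v, 0.0) + 1.0
        between[v][u] = between[v].get(u, 0.0) + 1.0

    q = modularity(g, list(members.values()))
    two_m = 2.0 * m
    merge_log: list[tuple[str, str, float, float]] = []

    while True:
        best_gain = 0.0
        best_pair: tuple[str, str] | None = None
        for i in sorted(between):
            di = degsum[i]
            for j, l_ij in between[i].items():
                if j <= i:
                    continue
                gain = l_ij / m - di * degsum[j] / (two_m * two_m / 2.0)
                if gain <= 1e-15:
                    continue
                if (
                    best_pair is None
                    or gain > best_gain + 1e-15
                    or (abs(gain - best_gain) <= 1e-15 and (i, j) < best_pair)
                ):
                    best_gain = gain
                    best_pair = (i, j)
        if best_pair is None:
            break
        i, j = best_pair
        q += best_gain
        _merge(members, degsum, between, i, j)
        merge_log.append((i, j, best_gain, q))

    comms = _sorted_communities(list(members.values()))
    final_q = modularity(g, comms)
    return Partition(communities=comms, q=final_q, merge_log=merge_log)


def _merge(
    members: dict[str, set[str]],
    degsum: dict[str, float],
    between: dict[str, dict[str, float]],
    i: str,
    j: str,
) -> None:
    """Merge community j into i (i < j, so i stays the merged label)."""
    members[i] |= members.pop(j)
    degsum[i] += degsum.pop(j)
    row_j = between.pop(j)
    row_i = between[i]
    row_i.pop(j, None)
    for k, l_jk in row_j.items():
        if k == i:
            continue
        row_i[k] = row_i.get(k, 0.0) + l_jk
        row_k = between[k]
        row_k.pop(j, None)
        row_k[i] = row_i[k]


def filter_communities(partition: Partition, min_size: int = 10) -> Partition:
    """Keep communities with at least ``min_size`` members.

    The biological-meaningfulness cutoff: tiny communities (often isolated
    seeds) carry no pathway signal. Discarded count is logged. The returned
    Partition keeps the original q (it scores the full partition on the
    full graph) and the original merge log.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [c for c in partition.communities if len(c) >= min_size]
    dropped = len(partition.communities) - len(kept)
    if dropped:
        logger.info(
            "filter_communities: dropped %d communities below size %d",
            dropped,
            min_size,
        )
    return Partition(communities=kept, q=partition.q, merge_log=partition.merge_log)
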