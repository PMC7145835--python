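"""Pathway over-representation: one-sided Fisher exact test + BH-FDR.

For a community of size ``s`` drawn from a background universe of ``N``
genes, a pathway of size ``K`` (within the background), and an observed
overlap of ``k`` genes, the enrichment p-value is the upper hypergeometric
tail

    p = sum_{i=k}^{min(K, s)}  C(K, i) C(N-K, s-i) / C(N, s),

the probability of an overlap at least as large under random draws. Only
over-representation is tested; depletion is not of interest here. All
(community x pathway) tests with k >= 1 are adjusted *jointly* by the
Benjamini-Hochberg step-up procedure.

The background universe defaults, at the pipeline level, to the analyzed
network's node set; pathways are intersected with the background before
testing so K and k are measured in the same universe as s and N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .community import Partition
from .io import GeneSet, PathwayCollection

__all__ = [
    "EnrichmentRow",
    "fisher_exact_greater",
    "bh_adjust",
    "enrich_communities",
]


@dataclass(frozen=True)
class EnrichmentRow:
    """One community x pathway test result."""

    community: int
    pathway: str
    pathway_id: str
    k: int  # overlap size
    K: int  # pathway size within background
    s: int  # community size within background
    N: int  # background size
    p: float
    q: float


def fisher_exact_greater(k: int, K: int, s: int, N: int) -> float:
    """Upper hypergeometric tail P(X >= k) for X ~ Hypergeom(N, K, s).

    Equivalent to the one-sided (enrichment direction) Fisher exact test
    on the 2x2 table with margins (K, N-K) x (s, N-s). k = 0 returns
    exactly 1.0: the tail then covers the whole support.
    """
    if not (0 <= K <= N and 0 <= s <= N):
        raise ValueError(f"require 0 <= K, s <= N; got K={K}, s={s}, N={N}")
    if not 0 <= k <= min(K, s):
        raise ValueError(f"require 0 <= k <= min(K, s); got k={k}, K={K}, s={s}")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates the sum of
    # pmf terms from log-gamma factorials
    return float(hypergeom.sf(k - 1, N, K, s))


def bh_adjust(p_values: list[float] | np.ndarray) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values (q-values).

    On the sorted p-values, q_(i) = min_{j >= i} m p_(j) / j, capped at 1,
    mapped back to the input order. Monotone by construction: sorting the
    output by the input p-values gives a non-decreasing sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q.tolist()


def enrich_communities(
    partition: Partition,
    pathways: PathwayCollection,
    background: GeneSet,
) -> list[EnrichmentRow]:
    """Test every (community, pathway) pair for over-representation.

    Community ids follow the partition's ordering. Pathways are first
    intersected with the background; pairs with zero overlap are not
    reported (and therefore do not enter the BH family -- the family is
    the emitted rows, adjusted in one joint pass). Rows come back sorted
    by (community, q, p, pathway).

    Every community member must be in the background; supplying a
    background that misses community genes indicates a universe mismatch
    and raises.
    """
    universe = frozenset(background.members)
    if not universe:
        raise ValueError("empty background universe")
    for comm in partition.communities:
        missing = comm - universe
        if missing:
            raise ValueError(
                f"community members outside background: {sorted(missing)[:5]}"
            )
    restricted = pathways.restricted_to(universe)
    N = len(universe)
    rows: list[EnrichmentRow] = []
    for cid, comm in enumerate(partition.communities):
        s = len(comm)
        for name in sorted(restricted.pathways):
            members = restricted.pathways[name]
            k = len(comm & members)
            if k == 0:
                continue
            p = fisher_exact_greater(k, len(members), s, N)
            rows.append(
                EnrichmentRow(
                    community=cid,
                    pathway=name,
                    pathway_id=restricted.source_ids.get(name, ""),
                    k=k,
                    K=len(members),
                    s=s,
                    N=N,
                    p=p,
                    q=float("nan"),
                )
            )
    if not rows:
        return []
    qs = bh_adjust([r.p for r in rows])
    rows = [
        EnrichmentRow(
            r.community, r.pathway, r.pathway_id, r.k, r.K, r.s, r.N, r.p, q
        )
        for r, q in zip(rows, qs)
    ]
    rows.sort(key=lambda r: (r.community, r.q, r.p, r.pathway))
    return rows
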