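"""Planted-partition benchmark generator for the triple-focusing analysis.

Real disease interactomes are not packaged here, so every downstream stage
is exercised on synthetic graphs whose ground truth is known by
construction:

* ``n_blocks`` dense blocks of ``block_size`` nodes each, wired internally
  with probability ``p_in`` and across blocks with probability ``p_out``
  (a planted-partition / stochastic-block-model graph);
* ``n_bridges`` designated bridge nodes that belong to *no* block but send
  ``bridge_degree`` edges into every block -- the synthetic analog of the
  high-betweenness "gateway" proteins the analysis is designed to surface;
* two disease gene sets A and B that both contain all bridges plus
  disjoint samples of block nodes, so A and B overlap exactly on the
  planted gateways;
* a smaller drug-perturbation set forced to contain ``drug_bridge_count``
  bridges, so the triple overlap A .. B .. drug contains known positives;
* one pathway per block (optionally noised) aligned with the planted
  communities, for testing enrichment recovery.

Edge confidence scores are drawn uniformly from [401, 1000] so the default
STRING medium-confidence filter (score > 400) keeps every synthetic edge
unless a test deliberately plants sub-threshold ones.

Determinism: a single integer seed drives independent named sub-streams
(edges / gene sets / pathways), derived as ``default_rng([seed, stage])``,
so adding a later stage never perturbs earlier draws and equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import GeneSet, InteractionRecord, PathwayCollection

__all__ = [
    "PlantedConfig",
    "PlantedTruth",
    "generate_planted_network",
    "generate_gene_sets",
    "generate_pathways",
    "generate_study",
    "write_truth",
]

_STAGE_EDGES = 0
_STAGE_SETS = 1
_STAGE_PATHWAYS = 2


@dataclass(frozen=True)
class PlantedConfig:
    """Generator parameters; defaults are the benchmark study conditions.

    The default geometry -- four blocks of 25 with p_in = 0.3 inside and
    p_out = 0.01 between, four bridges each sending three edges into every
    block -- gives blocks an expected internal degree of ~7 (well above the
    connectivity threshold) while keeping inter-block paths dominated by
    the bridges. Disease sets sample 40% of block nodes each, echoing the
    partial coverage of curated disease-gene lists; the drug set is an
    order of magnitude smaller than the disease sets, as perturbation
    panels typically are.
    """

    n_blocks: int = 4
    block_size: int = 25
    p_in: float = 0.3
    p_out: float = 0.01
    n_bridges: int = 4
    bridge_degree: int = 3
    set_a_frac: float = 0.4
    set_b_frac: float = 0.4
    drug_set_size: int = 12
    drug_bridge_count: int | None = None  # None -> all bridges
    seed: int = 0

    @property
    def resolved_drug_bridge_count(self) -> int:
        return self.n_bridges if self.drug_bridge_count is None else self.drug_bridge_count

    def validate(self) -> None:
        c = self
        if not (0.0 <= c.p_out < c.p_in <= 1.0):
            raise ValueError(
                f"require 0 <= p_out < p_in <= 1; got p_in={c.p_in}, p_out={c.p_out}"
            )
        for name in ("n_blocks", "block_size", "n_bridges", "bridge_degree",
                     "drug_set_size"):
            if getattr(c, name) < 1:
                raise ValueError(f"{name} must be positive")
        if c.n_blocks < 2:
            raise ValueError("need at least 2 blocks for bridges to bridge")
        if not (0.0 <= c.set_a_frac <= 1.0 and 0.0 <= c.set_b_frac <= 1.0):
            raise ValueError("set fractions must lie in [0, 1]")
        if not 0 <= c.resolved_drug_bridge_count <= min(c.n_bridges, c.drug_set_size):
            raise ValueError(
                "drug_bridge_count must be in [0, min(n_bridges, drug_set_size)]"
            )
        if c.n_bridges > c.drug_set_size:
            raise ValueError("n_bridges must not exceed drug_set_size")
        if c.bridge_degree > c.block_size:
            raise ValueError("bridge_degree cannot exceed block_size")
        if c.p_in * (c.block_size - 1) < 1.0:
            raise ValueError(
                "expected within-block degree below 1: blocks would be "
                "largely disconnected and betweenness recovery meaningless"
            )

    @property
    def n_nodes(self) -> int:
        return self.n_blocks * self.block_size + self.n_bridges


@dataclass
class PlantedTruth:
    """Ground truth of a planted benchmark instance."""

    block_of: dict[str, int]
    bridges: set[str]
    pathway_of_block: dict[int, str]
    set_a: frozenset[str] = field(default_factory=frozenset)
    set_b: frozenset[str] = field(default_factory=frozenset)
    drug_set: frozenset[str] = field(default_factory=frozenset)

    @property
    def blocks(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for node, b in self.block_of.items():
            out.setdefault(b, []).append(node)
        return [sorted(out[b]) for b in sorted(out)]

    @property
    def non_bridge_nodes(self) -> list[str]:
        return sorted(self.block_of)


def _symbols(total: int) -> list[str]:
    width = max(4, len(str(total)))
    return [f"G{i + 1:0{width}d}" for i in range(total)]


def generate_planted_network(
    config: PlantedConfig,
) -> tuple[list[InteractionRecord], PlantedTruth]:
    """Sample one planted-partition graph with bridge nodes.

    Returns the scored edge list plus the ground truth. Bridges connect to
    ``bridge_degree`` distinct nodes in *every* block and never to each
    other; block membership, bridge identity and the block->pathway naming
    are recorded in the truth object. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_EDGES])
    names = _symbols(config.n_nodes)
    block_nodes = [
        names[b * config.block_size : (b + 1) * config.block_size]
        for b in range(config.n_blocks)
    ]
    bridge_nodes = names[config.n_blocks * config.block_size :]

    edges: list[tuple[str, str]] = []
    # within-block edges
    for nodes in block_nodes:
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if rng.random() < config.p_in:
                    edges.append((nodes[i], nodes[j]))
    # sparse background edges between blocks (not via bridges)
    if config.p_out > 0.0:
        for b1 in range(config.n_blocks):
            for b2 in range(b1 + 1, config.n_blocks):
                for u in block_nodes[b1]:
                    for v in block_nodes[b2]:
                        if rng.random() < config.p_out:
                            edges.append((u, v))
    # bridges: bridge_degree stubs into each block
    for bridge in bridge_nodes:
        for nodes in block_nodes:
            targets = rng.choice(
                len(nodes), size=config.bridge_degree, replace=False
            )
            for t in sorted(targets):
                edges.append((bridge, nodes[t]))

    scores = rng.integers(401, 1001, size=len(edges))
    records = sorted(
        InteractionRecord(*((u, v) if u <= v else (v, u)), int(s))
        for (u, v), s in zip(edges, scores)
    )
    truth = PlantedTruth(
        block_of={
            node: b for b, nodes in enumerate(block_nodes) for node in nodes
        },
        bridges=set(bridge_nodes),
        pathway_of_block={
            b: f"PATHWAY_BLOCK_{b}" for b in range(config.n_blocks)
        },
    )
    return records, truth


def generate_gene_sets(
    truth: PlantedTruth, config: PlantedConfig
) -> tuple[GeneSet, GeneSet, GeneSet]:
    """Sample the two disease sets and the drug-perturbation set.

    Sets A and B each receive every bridge plus *disjoint* samples of the
    non-bridge nodes (so A and B intersect exactly on the bridges); the
    drug set receives ``drug_bridge_count`` bridges plus filler nodes drawn
    from the remaining non-bridge pool. Updates ``truth`` in place and
    returns the three :class:`GeneSet` objects.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_SETS])
    pool = truth.non_bridge_nodes
    bridges = sorted(truth.bridges)
    n_a = round(config.set_a_frac * len(pool))
    n_b = round(config.set_b_frac * len(pool))
    if n_a + n_b > len(pool):
        raise ValueError(
            f"set_a_frac + set_b_frac request {n_a + n_b} disjoint nodes "
            f"but only {len(pool)} non-bridge nodes exist"
        )
    perm = rng.permutation(len(pool))
    sample_a = {pool[i] for i in perm[:n_a]}
    sample_b = {pool[i] for i in perm[n_a : n_a + n_b]}

    drug_bridges = [
        bridges[i]
        for i in sorted(
            rng.choice(
                len(bridges),
                size=config.resolved_drug_bridge_count,
                replace=False,
            )
        )
    ]
    n_fill = config.drug_set_size - len(drug_bridges)
    if n_fill > len(pool):
        raise ValueError("drug_set_size exceeds available nodes")
    fill_idx = rng.choice(len(pool), size=n_fill, replace=False)
    drug = set(drug_bridges) | {pool[i] for i in sorted(fill_idx)}

    set_a = GeneSet("set_a", frozenset(sample_a | set(bridges)))
    set_b = GeneSet("set_b", frozenset(sample_b | set(bridges)))
    drug_set = GeneSet("drug_set", frozenset(drug))
    truth.set_a = set_a.members
    truth.set_b = set_b.members
    truth.drug_set = drug_set.members
    return set_a, set_b, drug_set


def generate_pathways(
    truth: PlantedTruth,
    noise_frac: float = 0.1,
    config: PlantedConfig | None = None,
) -> PathwayCollection:
    """One pathway per planted block, with ``noise_frac`` of members swapped.

    ``floor(noise_frac * block_size)`` members of each pathway are replaced
    by nodes from outside the block (other blocks or bridges), keeping the
    pathway size constant. ``noise_frac = 0`` reproduces the blocks
    exactly. Seeded from the same master seed as the graph (stage 2) when
    ``config`` is given, else from the default config seed 0.
    """
    if not 0.0 <= noise_frac < 0.5:
        raise ValueError(f"noise_frac must lie in [0, 0.5); got {noise_frac}")
    seed = config.seed if config is not None else 0
    rng = np.random.default_rng([seed, _STAGE_PATHWAYS])
    all_nodes = sorted(set(truth.block_of) | truth.bridges)
    coll = PathwayCollection()
    for b, block in enumerate(truth.blocks):
        name = truth.pathway_of_block[b]
        n_swap = int(noise_frac * len(block))
        members = set(block)
        if n_swap:
            out_idx = rng.choice(len(block), size=n_swap, replace=False)
            removed = {block[i] for i in sorted(out_idx)}
            outside = [v for v in all_nodes if v not in members]
            in_idx = rng.choice(len(outside), size=n_swap, replace=False)
            members = (members - removed) | {outside[i] for i in sorted(in_idx)}
        coll.pathways[name] = frozenset(members)
        coll.source_ids[name] = f"SYN{b:04d}"
    return coll


def generate_study(
    config: PlantedConfig, noise_frac: float = 0.1
) -> tuple[list[InteractionRecord], GeneSet, GeneSet, GeneSet, PathwayCollection, PlantedTruth]:
    """Convenience: one full benchmark instance (graph, sets, pathways, truth)."""
    records, truth = generate_planted_network(config)
    set_a, set_b, drug = generate_gene_sets(truth, config)
    pathways = generate_pathways(truth, noise_frac=noise_frac, config=config)
    return records, set_a, set_b, drug, pathways, truth


def with_seed(config: PlantedConfig, seed: int) -> PlantedConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Write ground truth as TSV: node, block (-1 for bridges), is_bridge."""
    path = Path(path)
    rows = [(v, truth.block_of[v], 0) for v in truth.non_bridge_nodes]
    rows += [(v, -1, 1) for v in sorted(truth.bridges)]
    rows.sort()
    with path.open("w") as fh:
        fh.write("node\tblock\tis_bridge\n")
        for v, b, isb in rows:
            fh.write(f"{v}\t{b}\t{isb}\n")
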