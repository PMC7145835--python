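"""End-to-end triple-focusing analysis.

The triple-focusing strategy nominates candidate drug targets by combining
three gene sets: two disease gene lists (say, two comorbid conditions) and
a drug-perturbation list. The pipeline

1. builds each disease network as the induced subgraph of the filtered
   interactome on its gene list,
2. joins them into a combined network (union of nodes and edges),
3. computes normalized degree and betweenness centrality on every network,
4. detects communities in the combined network by greedy modularity
   maximization, filters small ones, and maps the kept communities to
   pathways by Fisher/BH enrichment,
5. tabulates the pairwise disease-disease overlap with its combined-network
   centralities, and
6. ranks the overlap of the combined network with the drug set by
   betweenness -- the top of that ranking is the candidate-target list,
   nodes that sit between the two disease modules *and* respond to the
   drug.

Because disease networks are induced subgraphs that retain all seed genes,
the node overlap of two networks equals the set intersection of their gene
lists, and the combined-vs-drug overlap equals (A u B) n drug.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .centrality import CentralityTable, centrality_table, rank_nodes
from .community import Partition, filter_communities, greedy_modularity_communities
from .enrichment import EnrichmentRow, enrich_communities
from .graph import Graph, NetworkSummary, build_graph, node_overlap, union_graphs
from .io import GeneSet, InteractionRecord, PathwayCollection

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "TripleFocusReport",
    "run_triple_focus",
    "rank_overlap_by_betweenness",
    "write_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the analysis, mirroring the CLI flags."""

    min_confidence: float = 0.4  # STRING medium confidence, strict >
    min_community_size: int = 10
    top_k: int = 10
    seed: int = 0  # recorded in metadata; the analysis itself is deterministic

    def hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class TripleFocusReport:
    """Everything the analysis produces, ready for TSV export."""

    summaries: list[NetworkSummary]
    centrality: dict[str, CentralityTable]
    top_by_betweenness: dict[str, list[tuple[str, float, float]]]
    partition: Partition
    kept_partition: Partition
    enrichment: list[EnrichmentRow]
    pairwise_overlap: list[tuple[str, float, float]]
    triple_overlap: list[tuple[str, float, float]]
    metadata: dict = field(default_factory=dict)


def rank_overlap_by_betweenness(
    symbols: Sequence[str],
    table: CentralityTable,
    top_k: int | None = None,
) -> list[tuple[str, float, float]]:
    """Rows (symbol, C_D, C_B) sorted by betweenness desc, ties by symbol.

    Every symbol must exist in the table -- an unknown symbol usually means
    an un-normalized input list and is reported by name rather than
    silently dropped.
    """
    unknown = [s for s in symbols if s not in table.degree]
    if unknown:
        raise KeyError(
            f"symbols absent from centrality table: {', '.join(sorted(unknown))}"
        )
    rows = [(s, table.degree[s], table.betweenness[s]) for s in set(symbols)]
    rows.sort(key=lambda r: (-r[2], r[0]))
    if top_k is not None:
        rows = rows[: max(top_k, 0)]
    return rows


def run_triple_focus(
    set_a: GeneSet,
    set_b: GeneSet,
    records: Sequence[InteractionRecord],
    drug_set: GeneSet | None = None,
    pathways: PathwayCollection | None = None,
    config: PipelineConfig | None = None,
) -> TripleFocusReport:
    """Run the full analysis; see the module docstring for the stages.

    ``drug_set`` and ``pathways`` are optional: without a drug set the run
    is a two-network validation analysis (summaries, centralities,
    communities and the pairwise overlap only); without pathways the
    enrichment table is empty. An empty triple overlap produces a valid
    report with an empty ranked table and a warning, not a failure.
    """
    config = config or PipelineConfig()

    g_a = build_graph(records, set_a)
    g_b = build_graph(records, set_b)
    combined = union_graphs(g_a, g_b)
    assert combined.nodes == g_a.nodes | g_b.nodes
    logger.info(
        "networks: %s n=%d m=%d | %s n=%d m=%d | combined n=%d m=%d",
        set_a.name, g_a.n, g_a.m, set_b.name, g_b.n, g_b.m, combined.n, combined.m,
    )

    networks: dict[str, Graph] = {
        set_a.name: g_a,
        set_b.name: g_b,
        "combined": combined,
    }
    if drug_set is not None:
        networks[drug_set.name] = build_graph(records, drug_set)

    tables = {name: centrality_table(g) for name, g in networks.items()}
    summaries = [
        NetworkSummary(
            name,
            g.n,
            g.m,
            sum(tables[name].degree.values()) / g.n if g.n else 0.0,
            sum(tables[name].betweenness.values()) / g.n if g.n else 0.0,
        )
        for name, g in networks.items()
    ]
    top_tables = {
        name: rank_overlap_by_betweenness(
            rank_nodes(tables[name], "betweenness", config.top_k),
            tables[name],
        )
        for name, g in networks.items()
        if g.n
    }

    partition = greedy_modularity_communities(combined)
    kept = filter_communities(partition, config.min_community_size)
    logger.info(
        "communities: %d detected (Q=%.4f), %d kept at min size %d",
        len(partition), partition.q, len(kept), config.min_community_size,
    )
    enrichment: list[EnrichmentRow] = []
    if pathways is not None and len(kept) and combined.n:
        background = GeneSet("combined_network_nodes", frozenset(combined.nodes))
        enrichment = enrich_communities(kept, pathways, background)

    pair_symbols = node_overlap(set_a, set_b)
    pair_in_net = [s for s in pair_symbols if s in combined.nodes]
    assert set(pair_in_net) == set_a.members & set_b.members & combined.nodes
    pairwise = rank_overlap_by_betweenness(pair_in_net, tables["combined"])

    triple: list[tuple[str, float, float]] = []
    if drug_set is not None:
        triple_symbols = node_overlap(combined, drug_set)
        if not triple_symbols:
            logger.warning("combined network and drug set share no genes")
        triple = rank_overlap_by_betweenness(triple_symbols, tables["combined"])

    metadata = {
        "tool": "triplefocus",
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "min_confidence": config.min_confidence,
        "min_community_size": config.min_community_size,
        "top_k": config.top_k,
        "n_records": len(records),
        "networks": {name: {"n": g.n, "m": g.m} for name, g in networks.items()},
    }
    return TripleFocusReport(
        summaries=summaries,
        centrality=tables,
        top_by_betweenness=top_tables,
        partition=partition,
        kept_partition=kept,
        enrichment=enrichment,
        pairwise_overlap=pairwise,
        triple_overlap=triple,
        metadata=metadata,
    )


def _write_ranked(path: Path, rows: list[tuple[str, float, float]]) -> None:
    with path.open("w") as fh:
        fh.write("gene\tdegree_centrality\tbetweenness_centrality\n")
        for sym, cd, cb in rows:
            fh.write(f"{sym}\t{cd:.10g}\t{cb:.10g}\n")


def write_report(report: TripleFocusReport, outdir: str | Path) -> None:
    """Write every table of the report as TSV under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with (outdir / "network_summaries.tsv").open("w") as fh:
        fh.write(
            "network\tn_nodes\tn_edges\tmean_degree_centrality"
            "\tmean_betweenness_centrality\n"
        )
        for s in report.summaries:
            t = s.truncated()
            fh.write(
                f"{s.name}\t{s.n}\t{s.m}\t{t.mean_degree_centrality:.10g}"
                f"\t{t.mean_betweenness_centrality:.10g}\n"
            )

    for name, table in report.centrality.items():
        rows = rank_overlap_by_betweenness(sorted(table.degree), table)
        _write_ranked(outdir / f"centrality_{name}.tsv", rows)
    for name, rows in report.top_by_betweenness.items():
        _write_ranked(outdir / f"top_{name}.tsv", rows)
    _write_ranked(outdir / "pairwise_overlap.tsv", report.pairwise_overlap)
    _write_ranked(outdir / "triple_overlap.tsv", report.triple_overlap)

    with (outdir / "communities.tsv").open("w") as fh:
        fh.write("gene\tcommunity_id\n")
        cof = report.partition.community_of
        for gene in sorted(cof):
            fh.write(f"{gene}\t{cof[gene]}\n")

    with (outdir / "enrichment.tsv").open("w") as fh:
        fh.write("community\tpathway\tpathway_id\tk\tK\ts\tN\tp\tq\n")
        for r in report.enrichment:
            fh.write(
                f"{r.community}\t{r.pathway}\t{r.pathway_id}\t{r.k}\t{r.K}"
                f"\t{r.s}\t{r.N}\t{r.p:.10g}\t{r.q:.10g}\n"
            )

    import yaml

    with (outdir / "run_metadata.yaml").open("w") as fh:
        yaml.safe_dump(report.metadata, fh, sort_keys=True)
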