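"""Readers and writers for the plain-text formats the pipeline consumes.

Three input formats are supported:

* **Edge lists** in the STRING dialect: tab-separated ``protein_a``,
  ``protein_b``, ``combined_score`` with scores on the 0-1000 integer scale.
  An optional header row is auto-detected.
* **Gene lists**: one symbol per line, ``#`` comments allowed.
* **GMT** pathway collections: ``name<TAB>description<TAB>member...``.

Gene symbols are whitespace-trimmed and upper-cased everywhere, so the same
protein named in different case in different files maps to one node. No
alias or cross-database identifier resolution is attempted; inputs are
assumed to be pre-mapped to a single symbol namespace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "GeneSet",
    "PathwayCollection",
    "ParseError",
    "read_edge_list",
    "read_gene_list",
    "read_gmt",
    "write_edge_list",
    "write_gene_list",
    "write_gmt",
]


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


@dataclass(frozen=True, order=True)
class InteractionRecord:
    """One scored protein-protein interaction.

    Scores follow the STRING ``combined_score`` convention: integers in
    [0, 1000], where 1000 corresponds to confidence 1.0.
    """

    node_a: str
    node_b: str
    score: int

    def __post_init__(self) -> None:
        if not self.node_a or not self.node_b:
            raise ValueError("interaction endpoints must be non-empty symbols")
        if self.node_a == self.node_b:
            raise ValueError(f"self-interaction not representable: {self.node_a}")
        if not 0 <= self.score <= 1000:
            raise ValueError(f"score {self.score} outside [0, 1000]")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered endpoint pair in canonical (sorted) order."""
        a, b = self.node_a, self.node_b
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (a disease list, a drug-perturbation list)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    @classmethod
    def from_iterable(cls, name: str, symbols: Iterable[str]) -> "GeneSet":
        members = frozenset(_normalize(s) for s in symbols if _normalize(s))
        return cls(name=name, members=members)


@dataclass
class PathwayCollection:
    """Named pathway gene sets plus a source identifier per pathway."""

    pathways: dict[str, frozenset[str]] = field(default_factory=dict)
    source_ids: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def items(self):
        return self.pathways.items()

    def restricted_to(self, universe: frozenset[str]) -> "PathwayCollection":
        """Intersect every pathway with ``universe``; empty pathways are dropped."""
        out = PathwayCollection()
        for name, members in self.pathways.items():
            kept = members & universe
            if kept:
                out.pathways[name] = kept
                out.source_ids[name] = self.source_ids.get(name, "")
        return out


def _normalize(symbol: str) -> str:
    return symbol.strip().upper()


def read_edge_list(
    path: str | Path, min_confidence: float = 0.4
) -> list[InteractionRecord]:
    """Read a STRING-dialect TSV edge list, filter, and deduplicate.

    Parameters
    ----------
    path:
        Tab-separated file with at least three columns: two symbols and an
        integer score in [0, 1000]. A header row is detected by a
        non-integer third field on the first line.
    min_confidence:
        Confidence threshold on the 0-1 scale. Records are kept only if
        ``score > min_confidence * 1000`` -- strictly greater, so the STRING
        "medium confidence" cutoff of 0.4 drops a score of exactly 400.

    Returns
    -------
    Sorted list of :class:`InteractionRecord`. Self-loops are dropped (with
    a logged count), duplicate unordered pairs are collapsed keeping the
    maximum score.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    best: dict[tuple[str, str], int] = {}
    n_self = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if lineno == 1 and not _is_int(fields[2]):
                continue  # header row
            a, b = _normalize(fields[0]), _normalize(fields[1])
            if not a or not b:
                raise ParseError(f"{path}:{lineno}: empty gene symbol")
            if not _is_int(fields[2]):
                raise ParseError(
                    f"{path}:{lineno}: non-integer score {fields[2]!r}"
                )
            score = int(fields[2])
            if not 0 <= score <= 1000:
                raise ParseError(f"{path}:{lineno}: score {score} outside 0-1000")
            if a == b:
                n_self += 1
                continue
            pair = (a, b) if a <= b else (b, a)
            if score > best.get(pair, -1):
                best[pair] = score

    if n_self:
        logger.info("%s: dropped %d self-loop rows", path.name, n_self)
    cutoff = min_confidence * 1000.0
    records = [
        InteractionRecord(a, b, s) for (a, b), s in best.items() if s > cutoff
    ]
    records.sort()
    return records


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


def read_gene_list(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list into a :class:`GeneSet`.

    Lines starting with ``#`` are comments. Symbols are trimmed, upper-cased
    and de-duplicated (duplicate count is logged). An empty result is an
    error -- a pipeline fed an empty disease list is misconfigured.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = name or path.stem
    seen: set[str] = set()
    n_dup = 0
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            symbol = _normalize(line)
            if symbol in seen:
                n_dup += 1
            else:
                seen.add(symbol)
    if n_dup:
        logger.info("%s: %d duplicate symbols collapsed", path.name, n_dup)
    if not seen:
        raise ParseError(f"{path}: no gene symbols found")
    return GeneSet(name=name, members=frozenset(seen))


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT file: ``name<TAB>source_id/description<TAB>members...``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    coll = PathwayCollection()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >=3 fields, got {len(fields)}"
                )
            pw_name = fields[0].strip()
            if not pw_name:
                raise ParseError(f"{path}:{lineno}: empty pathway name")
            if pw_name in coll.pathways:
                raise ParseError(f"{path}:{lineno}: duplicate pathway {pw_name!r}")
            members = frozenset(
                _normalize(f) for f in fields[2:] if _normalize(f)
            )
            if not members:
                raise ParseError(f"{path}:{lineno}: pathway {pw_name!r} is empty")
            coll.pathways[pw_name] = members
            coll.source_ids[pw_name] = fields[1].strip()
    return coll


def write_edge_list(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records as STRING-dialect TSV with a header row."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for rec in sorted(records):
            fh.write(f"{rec.node_a}\t{rec.node_b}\t{rec.score}\n")


def write_gene_list(gene_set: GeneSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for symbol in sorted(gene_set.members):
            fh.write(symbol + "\n")


def write_gmt(
    collection: PathwayCollection | Mapping[str, frozenset[str]],
    path: str | Path,
) -> None:
    """Write pathways in GMT format, members in sorted order."""
    if isinstance(collection, PathwayCollection):
        pathways = collection.pathways
        source_ids = collection.source_ids
    else:
        pathways = dict(collection)
        source_ids = {}
    path = Path(path)
    with path.open("w") as fh:
        for name in sorted(pathways):
            desc = source_ids.get(name, "na") or "na"
            members = "\t".join(sorted(pathways[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")
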