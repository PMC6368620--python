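"""Scored protein-protein interaction networks.

Parses HIPPIE-style tab-delimited interaction tables, filters them by
confidence score, and builds an undirected simple graph that every
downstream statistic (localization, separation, DIAMOnD) operates on.
All distances in this package are unweighted hop counts.
"""

from __future__ import annotations

import math
import re
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import networkx as nx

__all__ = [
    "InteractionRecord",
    "Interactome",
    "ParseResult",
    "parse_hippie",
    "filter_by_confidence",
    "build_graph",
    "shortest_distances",
    "degree_histogram",
    "read_gene_list",
    "write_edge_list",
]

_HUMAN_TOKENS = {"9606", "human", "homo sapiens"}
_SPECIES_RE = re.compile(r"species:([^;|]*)", re.IGNORECASE)


@dataclass(frozen=True)
class InteractionRecord:
    """One scored interaction between two gene/protein identifiers."""

    protein_a: str
    protein_b: str
    confidence: float
    annotation: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"confidence must lie in [0, 1], got {self.confidence!r}"
            )


@dataclass
class ParseResult:
    """Records plus bookkeeping for rows the parser had to skip."""

    records: list[InteractionRecord]
    n_skipped: int = 0
    n_nonhuman: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[InteractionRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]


def _symbol_from_name(name: str) -> str:
    """Gene symbol from a UniProt-style entry name (text before ``_HUMAN``)."""
    return name.split("_", 1)[0] if name else name


def _resolve_identifier(
    name: str, entrez: str, mapping: Mapping[str, str] | None
) -> str | None:
    """Primary key is the Entrez id when present; symbol otherwise.

    An explicit two-column mapping overrides both, keyed on either the raw
    name or the raw Entrez id.
    """
    if mapping:
        if name in mapping:
            return mapping[name]
        if entrez in mapping:
            return mapping[entrez]
    entrez = entrez.strip()
    if entrez and entrez not in {"-", "0", "NA"}:
        return entrez
    sym = _symbol_from_name(name.strip())
    return sym or None


def _is_human(annotation: str) -> bool:
    m = _SPECIES_RE.search(annotation)
    if m is None:
        return True  # no species tag: assume human
    values = {v.strip().lower() for v in m.group(1).split(",") if v.strip()}
    return not values or bool(values & _HUMAN_TOKENS)


def parse_hippie(
    stream: IO[str] | Iterable[str],
    strict: bool = False,
    mapping: Mapping[str, str] | None = None,
) -> ParseResult:
    """Parse a HIPPIE-style TSV into interaction records.

    Expected columns (tab-separated, no header required):
    name A, Entrez A, name B, Entrez B, confidence score, annotation.
    Rows with unparseable identifiers or confidence are skipped and counted;
    with ``strict`` on, rows whose annotation tags a non-human species are
    skipped and counted separately.
    """
    records: list[InteractionRecord] = []
    n_skipped = 0
    n_nonhuman = 0
    saw_row = False
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if not saw_row:
            saw_row = True
            if len(fields) < 5:
                raise ValueError(
                    "missing confidence column: expected a numeric score in "
                    "column 5 of a >=6-column HIPPIE table"
                )
        if len(fields) < 5:
            n_skipped += 1
            continue
        annotation = fields[5] if len(fields) > 5 else ""
        if strict and not _is_human(annotation):
            n_nonhuman += 1
            continue
        a = _resolve_identifier(fields[0], fields[1], mapping)
        b = _resolve_identifier(fields[2], fields[3], mapping)
        try:
            conf = float(fields[4])
        except ValueError:
            conf = math.nan
        if a is None or b is None or not (0.0 <= conf <= 1.0):
            n_skipped += 1
            continue
        records.append(InteractionRecord(a, b, conf, annotation))
    if not saw_row:
        raise ValueError("empty interaction stream")
    return ParseResult(records, n_skipped=n_skipped, n_nonhuman=n_nonhuman)


def filter_by_confidence(
    records: Iterable[InteractionRecord], threshold: float
) -> list[InteractionRecord]:
    """Keep records with confidence >= threshold (inclusive), order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold!r}")
    return [r for r in records if r.confidence >= threshold]


class Interactome:
    """Undirected simple graph of scored interactions.

    Thin wrapper around :class:`networkx.Graph` that caches a plain
    ``dict[node, set[node]]`` adjacency for the breadth-first searches the
    statistics run millions of times.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        self._adj: dict[str, set[str]] | None = None

    # -- container protocol -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    @property
    def adj(self) -> dict[str, set[str]]:
        if self._adj is None:
            self._adj = {u: set(nbrs) for u, nbrs in self.graph.adjacency()}
        return self._adj

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def confidence(self, u: str, v: str) -> float:
        return self.graph.edges[u, v].get("confidence", 1.0)

    def edge_records(self) -> list[InteractionRecord]:
        """Dump the graph back to records (lexicographically sorted pairs)."""
        out = []
        for u, v, data in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append(InteractionRecord(a, b, data.get("confidence", 1.0)))
        out.sort(key=lambda r: (r.protein_a, r.protein_b))
        return out


def build_graph(records: Iterable[InteractionRecord]) -> Interactome:
    """Build the interactome: drop self-loops, collapse duplicates (max score)."""
    g = nx.Graph()
    for r in records:
        if r.protein_a == r.protein_b:
            continue
        u, v = r.protein_a, r.protein_b
        if g.has_edge(u, v):
            if r.confidence > g.edges[u, v]["confidence"]:
                g.edges[u, v]["confidence"] = r.confidence
        else:
            g.add_edge(u, v, confidence=r.confidence)
    if g.number_of_edges() == 0:
        raise ValueError("no edges survive self-loop/duplicate filtering")
    return Interactome(g)


def bfs_nearest(
    adj: Mapping[str, set[str]],
    source: str,
    targets: set[str],
    skip_self: bool = False,
) -> float:
    """Hop distance from ``source`` to the nearest member of ``targets``.

    Early-exit BFS; returns ``math.inf`` when no target is reachable.
    With ``skip_self`` the source itself does not count as a hit.
    """
    if source in targets and not skip_self:
        return 0
    seen = {source}
    frontier = deque([(source, 0)])
    while frontier:
        u, d = frontier.popleft()
        for w in adj[u]:
            if w in seen:
                continue
            if w in targets:
                return d + 1
            seen.add(w)
            frontier.append((w, d + 1))
    return math.inf


def shortest_distances(
    g: Interactome,
    sources: Iterable[str],
    targets: Iterable[str],
    skip_self: bool = False,
) -> dict[str, float]:
    """Minimum hop distance from each source to any target.

    Unreachable sources map to ``math.inf`` (never silently dropped).
    ``skip_self`` excludes a source from acting as its own target, which is
    the convention the nearest-other-seed statistics need.
    """
    sources = list(sources)
    target_set = set(targets)
    missing = [s for s in sources if s not in g] + [
        t for t in target_set if t not in g
    ]
    if missing:
        raise KeyError(
            f"identifiers not in the interactome: {sorted(set(missing))}"
        )
    return {
        s: bfs_nearest(g.adj, s, target_set, skip_self=skip_self)
        for s in sources
    }


def degree_histogram(g: Interactome) -> dict[int, int]:
    """Map degree -> node count; values sum to the node count."""
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    return dict(Counter(d for _, d in g.graph.degree()))


def read_gene_list(stream: IO[str] | Iterable[str]) -> list[str]:
    """One identifier per line; '#' starts a comment; order preserved."""
    out = []
    for raw in stream:
        line = raw.split("#", 1)[0].strip()
        if line:
            out.append(line)
    return out


def write_edge_list(g: Interactome, stream: IO[str]) -> None:
    """3-column TSV (node_a, node_b, confidence), lexicographically sorted."""
    for r in g.edge_records():
        stream.write(f"{r.protein_a}\t{r.protein_b}\t{r.confidence:g}\n")
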