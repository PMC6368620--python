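"""Module-set algebra and pathway over-representation analysis (ORA).

Given two expanded disease modules, six gene sets are analyzed: each module,
their intersection (the shared "core"), their union (the disease "spectrum"),
and the two differences. Every set is tested against GMT pathway collections
with a hypergeometric upper-tail test, corrected by Benjamini-Hochberg FDR
(significance cut FDR <= 0.2), and the significant pathways are grouped into
components of a Jaccard-similarity graph (J > 0.1). Finally each pathway is
assigned to the disease module that dominates its signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping

import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diamond import ExpandedModule

__all__ = [
    "ModuleSets",
    "PathwayDB",
    "EnrichmentRow",
    "module_sets",
    "parse_gmt",
    "write_gmt",
    "ora",
    "filter_fdr",
    "pathway_jaccard_groups",
    "assign_dominance",
]


@dataclass(frozen=True)
class ModuleSets:
    """The six gene sets derived from two expanded disease modules."""

    cmt2: frozenset[str]
    hsp: frozenset[str]
    core: frozenset[str]
    spectrum: frozenset[str]
    cmt2_only: frozenset[str]
    hsp_only: frozenset[str]

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "cmt2": len(self.cmt2),
            "hsp": len(self.hsp),
            "core": len(self.core),
            "spectrum": len(self.spectrum),
            "cmt2_only": len(self.cmt2_only),
            "hsp_only": len(self.hsp_only),
        }

    def as_dict(self) -> dict[str, frozenset[str]]:
        return {
            "cmt2": self.cmt2,
            "hsp": self.hsp,
            "core": self.core,
            "spectrum": self.spectrum,
            "cmt2_only": self.cmt2_only,
            "hsp_only": self.hsp_only,
        }


def _as_set(x) -> frozenset[str]:
    if isinstance(x, ExpandedModule):
        return frozenset(x.all_members)
    return frozenset(x)


def module_sets(cmt2_expanded, hsp_expanded) -> ModuleSets:
    """Intersection/union/difference algebra over two expanded modules."""
    a, b = _as_set(cmt2_expanded), _as_set(hsp_expanded)
    if not a or not b:
        raise ValueError("both expanded modules must be non-empty")
    return ModuleSets(
        cmt2=a,
        hsp=b,
        core=a & b,
        spectrum=a | b,
        cmt2_only=a - b,
        hsp_only=b - a,
    )


@dataclass
class PathwayDB:
    """Named gene sets (GMT collections) with source tags."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    sources: dict[str, str] = field(default_factory=dict)

    def harmonized(self, background: frozenset[str]) -> "PathwayDB":
        """Restrict every set to the background; drop sets that empty out."""
        kept, desc, src = {}, {}, {}
        for name, genes in self.sets.items():
            inter = genes & background
            if inter:
                kept[name] = inter
                desc[name] = self.descriptions.get(name, "")
                src[name] = self.sources.get(name, "")
        return PathwayDB(kept, desc, src)

    def merge(self, other: "PathwayDB") -> "PathwayDB":
        sets = {**self.sets, **other.sets}
        return PathwayDB(
            sets,
            {**self.descriptions, **other.descriptions},
            {**self.sources, **other.sources},
        )


def parse_gmt(stream: IO[str] | Iterable[str], source: str = "") -> PathwayDB:
    """Parse a GMT file: name TAB description TAB gene [TAB gene ...]."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    src: dict[str, str] = {}
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip():
            warnings.warn(f"GMT line {lineno}: empty, skipped", stacklevel=2)
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"GMT line {lineno}: expected name, description and at least "
                f"one gene, got {len(fields)} field(s)"
            )
        name = fields[0]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            raise ValueError(f"GMT line {lineno}: pathway {name!r} has no genes")
        sets[name] = genes
        desc[name] = fields[1]
        src[name] = source
    return PathwayDB(sets, desc, src)


def write_gmt(db: PathwayDB, stream: IO[str]) -> None:
    for name in sorted(db.sets):
        genes = "\t".join(sorted(db.sets[name]))
        stream.write(f"{name}\t{db.descriptions.get(name, '')}\t{genes}\n")


@dataclass
class EnrichmentRow:
    pathway: str
    source: str
    overlap: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    fdr: float
    enrichment_ratio: float
    overlap_genes: frozenset[str] = frozenset()


def ora(
    query: Iterable[str],
    db: PathwayDB,
    background: Iterable[str],
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of a query set in each pathway.

    For a pathway of size K inside a background of size B, the p-value is
    P(X >= overlap) for |query| draws without replacement; the enrichment
    ratio is (overlap/|query|) / (K/B). FDR is Benjamini-Hochberg across all
    tested pathways. Rows are returned sorted by p-value.
    """
    bg = frozenset(background)
    q = frozenset(query) & bg
    if not q:
        raise ValueError("query does not intersect the background universe")
    harmonized = db.harmonized(bg)
    if not harmonized.sets:
        return []
    names = sorted(harmonized.sets)
    B, Q = len(bg), len(q)
    rows: list[EnrichmentRow] = []
    pvals: list[float] = []
    for name in names:
        genes = harmonized.sets[name]
        K = len(genes)
        hits = q & genes
        ov = len(hits)
        p = float(stats.hypergeom.sf(ov - 1, B, K, Q)) if ov > 0 else 1.0
        ratio = (ov / Q) / (K / B) if ov > 0 else 0.0
        pvals.append(min(1.0, p))
        rows.append(
            EnrichmentRow(
                pathway=name,
                source=harmonized.sources.get(name, ""),
                overlap=ov,
                set_size=K,
                query_size=Q,
                background_size=B,
                p_value=min(1.0, p),
                fdr=1.0,
                enrichment_ratio=ratio,
                overlap_genes=hits,
            )
        )
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    for row, f in zip(rows, fdrs):
        row.fdr = float(max(f, row.p_value))
    rows.sort(key=lambda r: (r.p_value, r.pathway))
    return rows


def filter_fdr(
    rows: Iterable[EnrichmentRow], threshold: float = 0.2
) -> list[EnrichmentRow]:
    """Keep rows with FDR <= threshold (inclusive)."""
    return [r for r in rows if r.fdr <= threshold]


def pathway_jaccard_groups(
    significant: Iterable[EnrichmentRow],
    db: PathwayDB,
    j_min: float = 0.1,
) -> list[list[str]]:
    """Group significant pathways by gene overlap.

    Two pathways are linked when their Jaccard coefficient strictly exceeds
    ``j_min``; groups are the connected components, largest first.
    """
    names = sorted({r.pathway for r in significant})
    if not names:
        raise ValueError("no significant pathways to group")
    g = nx.Graph()
    g.add_nodes_from(names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            sa, sb = db.sets[a], db.sets[b]
            j = len(sa & sb) / len(sa | sb)
            if j > j_min:
                g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    return comps


def assign_dominance(
    results_by_set: Mapping[str, Iterable[EnrichmentRow]],
    fdr_threshold: float = 0.2,
) -> dict[str, str]:
    """Assign each enriched pathway to its most influenced disease module.

    Decision table over the six module sets (significant = FDR <= threshold):

    ========================  =========================  =============
    significant in cmt2_only  significant in hsp_only    label
    ========================  =========================  =============
    yes                       no                         CMT2-dominant
    no                        yes                        HSP-dominant
    yes                       yes                        AXONO
    no                        no (but sig. elsewhere)    AXONO
    ========================  =========================  =============

    Pathways significant in no set are excluded from the result.
    """
    sig: dict[str, set[str]] = {}
    for set_name, rows in results_by_set.items():
        for r in rows:
            if r.fdr <= fdr_threshold:
                sig.setdefault(r.pathway, set()).add(set_name)
    out: dict[str, str] = {}
    for pathway, where in sig.items():
        in_cmt2_only = "cmt2_only" in where
        in_hsp_only = "hsp_only" in where
        if in_cmt2_only and not in_hsp_only:
            out[pathway] = "CMT2-dominant"
        elif in_hsp_only and not in_cmt2_only:
            out[pathway] = "HSP-dominant"
        else:
            out[pathway] = "AXONO"
    return out
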