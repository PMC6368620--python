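"""Wang-method GO semantic similarity for module validation.

The Wang measure scores two ontology terms by propagating "S-values" from
each term up through its ancestor closure: the term itself contributes 1 and
every ancestor contributes the best relation-weighted product along a path
down to the term (is_a edges weigh 0.8, part_of 0.6). The similarity of two
terms is the summed S-value mass they share over their total mass. Gene-level
similarity combines the term-pair matrix with the best-match average (BMA):
the mean of all row maxima and column maxima.

Annotation quality is controlled by evidence-code filtering; electronic
(IEA) and physical-interaction (IPI) annotations are excluded by default
because the genes being validated come from a physical-interaction network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "GODag",
    "AnnotationSet",
    "WANG_WEIGHTS",
    "filter_evidence",
    "svalues",
    "term_sim_wang",
    "gene_sim_bma",
    "semsim_matrix",
    "cluster_semsim",
    "read_gaf",
]

WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}

_ASPECT_TO_NAMESPACE = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}


class GODag:
    """A typed is_a/part_of term DAG supporting S-value propagation."""

    def __init__(
        self,
        terms: Mapping[str, str],
        edges: Iterable[tuple[str, str, str]],
    ):
        """``terms`` maps term id -> namespace; ``edges`` are
        (child, parent, relation) triples with relation in {is_a, part_of}.
        Other relations should be dropped by the caller (see ``from_obo``).
        """
        self.namespace = dict(terms)
        self.parents: dict[str, tuple[tuple[str, str], ...]] = {
            t: () for t in self.namespace
        }
        tmp: dict[str, list[tuple[str, str]]] = {}
        for child, parent, rel in edges:
            if rel not in WANG_WEIGHTS:
                raise ValueError(f"unsupported relation {rel!r}")
            if child not in self.namespace or parent not in self.namespace:
                raise KeyError(f"edge {child}->{parent} references unknown term")
            tmp.setdefault(child, []).append((parent, rel))
        for child, ps in tmp.items():
            self.parents[child] = tuple(ps)
        self._check_acyclic()
        self._closure_cache: dict[str, frozenset[str]] = {}

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p, _ in self.parents[t]:
                s = state.get(p)
                if s == 1:
                    raise ValueError(f"cycle in ontology at term {t}")
                if s is None:
                    visit(p)
            state[t] = 2

        for t in self.namespace:
            if t not in state:
                visit(t)

    def __contains__(self, term: str) -> bool:
        return term in self.namespace

    def __len__(self) -> int:
        return len(self.namespace)

    @property
    def roots(self) -> dict[str, list[str]]:
        """Namespace -> terms without parents."""
        out: dict[str, list[str]] = {}
        for t, ns in self.namespace.items():
            if not self.parents[t]:
                out.setdefault(ns, []).append(t)
        return {ns: sorted(ts) for ns, ts in out.items()}

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of a term, the term itself included."""
        cached = self._closure_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.namespace:
            raise KeyError(f"term {term!r} not in the DAG")
        out = {term}
        stack = [term]
        while stack:
            t = stack.pop()
            for p, _ in self.parents[t]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        result = frozenset(out)
        self._closure_cache[term] = result
        return result

    @classmethod
    def from_obo(cls, path_or_stream) -> "GODag":
        """Load an OBO 1.2 flat file (via obonet), keeping is_a and part_of.

        Obsolete terms are excluded by obonet; edges with other relation
        types are counted on ``n_ignored_relations``.
        """
        import obonet

        g = obonet.read_obo(path_or_stream)
        terms = {
            t: data.get("namespace", "biological_process")
            for t, data in g.nodes(data=True)
        }
        edges = []
        ignored = 0
        for child, parent, rel in g.edges(keys=True):
            if rel in WANG_WEIGHTS:
                edges.append((child, parent, rel))
            else:
                ignored += 1
        dag = cls(terms, edges)
        dag.n_ignored_relations = ignored
        return dag


@dataclass
class AnnotationSet:
    """Gene -> set of (GO term, evidence code) pairs."""

    annotations: dict[str, set[tuple[str, str]]]
    flagged_genes: tuple[str, ...] = ()

    def genes(self) -> list[str]:
        return sorted(self.annotations)

    def terms_for(
        self,
        gene: str,
        dag: GODag | None = None,
        namespace: str | None = None,
    ) -> set[str]:
        terms = {t for t, _ in self.annotations.get(gene, set())}
        if dag is not None:
            terms = {t for t in terms if t in dag}
            if namespace is not None:
                terms = {t for t in terms if dag.namespace[t] == namespace}
        return terms


def read_gaf(stream: IO[str] | Iterable[str]) -> AnnotationSet:
    """Parse a GAF 2.x annotation file.

    Uses columns 2 (gene id), 5 (GO term), 7 (evidence code) and 9 (aspect);
    the aspect is kept as part of the term's implied namespace only insofar
    as the DAG carries it. Comment lines start with '!'.
    """
    annots: dict[str, set[tuple[str, str]]] = {}
    for raw in stream:
        if not raw.strip() or raw.startswith("!"):
            continue
        f = raw.rstrip("\n").split("\t")
        if len(f) < 9:
            continue
        gene, term, evidence = f[1], f[4], f[6]
        if not gene or not term:
            continue
        annots.setdefault(gene, set()).add((term, evidence))
    return AnnotationSet(annots)


def filter_evidence(
    annotations: AnnotationSet, excluded: set[str] = frozenset({"IEA", "IPI"})
) -> AnnotationSet:
    """Drop annotation pairs with excluded evidence codes.

    Genes left with no annotation are removed from the mapping and listed in
    ``flagged_genes`` so downstream matrices can report them rather than
    silently shrinking.
    """
    kept: dict[str, set[tuple[str, str]]] = {}
    flagged: list[str] = []
    for gene, pairs in annotations.annotations.items():
        surviving = {(t, e) for t, e in pairs if e not in excluded}
        if surviving:
            kept[gene] = surviving
        else:
            flagged.append(gene)
    return AnnotationSet(kept, flagged_genes=tuple(sorted(flagged)))


def svalues(
    term: str, dag: GODag, weights: Mapping[str, float] = WANG_WEIGHTS
) -> dict[str, float]:
    """Wang S-values of a term over its ancestor closure.

    S(term) = 1; for an ancestor t, S(t) is the maximum over its children t'
    inside the closure of w(t' -> t) * S(t'). The max (not a sum) is what
    keeps multi-path DAGs bounded by 1.
    """
    closure = dag.ancestors(term)
    # topological order of the closure, children before parents
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(t: str) -> None:
        state[t] = 1
        for p, _ in dag.parents[t]:
            if p in closure and state.get(p) is None:
                visit(p)
        state[t] = 2
        order.append(t)

    visit(term)
    # DFS post-order appends a node after all its ancestors, so the reversed
    # order visits children before their parents — safe for max-relaxation
    s = {t: 0.0 for t in closure}
    s[term] = 1.0
    for t in reversed(order):
        for p, rel in dag.parents[t]:
            if p in closure:
                cand = weights[rel] * s[t]
                if cand > s[p]:
                    s[p] = cand
    return s


def term_sim_wang(
    a: str,
    b: str,
    dag: GODag,
    weights: Mapping[str, float] = WANG_WEIGHTS,
) -> float:
    """Wang similarity of two terms in the same namespace, in [0, 1]."""
    for t in (a, b):
        if t not in dag:
            raise KeyError(f"term {t!r} not in the DAG")
    if dag.namespace[a] != dag.namespace[b]:
        raise ValueError(
            f"terms {a} ({dag.namespace[a]}) and {b} ({dag.namespace[b]}) "
            "are in different namespaces"
        )
    sa = svalues(a, dag, weights)
    sb = svalues(b, dag, weights)
    common = sa.keys() & sb.keys()
    num = sum(sa[t] + sb[t] for t in common)
    den = sum(sa.values()) + sum(sb.values())
    return min(1.0, num / den) if den > 0 else 0.0


def gene_sim_bma(
    g1: str,
    g2: str,
    annotations: AnnotationSet,
    dag: GODag,
    namespace: str = "biological_process",
    weights: Mapping[str, float] = WANG_WEIGHTS,
) -> float:
    """Best-match-average Wang similarity of two genes.

    BMA = (sum of row maxima + sum of column maxima) / (n_rows + n_cols)
    over the term-pair similarity matrix of the two genes' annotations in
    the requested namespace.
    """
    t1 = sorted(annotations.terms_for(g1, dag, namespace))
    t2 = sorted(annotations.terms_for(g2, dag, namespace))
    for gene, terms in ((g1, t1), (g2, t2)):
        if not terms:
            raise ValueError(
                f"gene {gene!r} has no surviving {namespace} annotation"
            )
    m = np.array([[term_sim_wang(x, y, dag, weights) for y in t2] for x in t1])
    return float(
        (m.max(axis=1).sum() + m.max(axis=0).sum()) / (m.shape[0] + m.shape[1])
    )


def semsim_matrix(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    annotations: AnnotationSet,
    dag: GODag,
    namespace: str = "biological_process",
) -> pd.DataFrame:
    """BMA similarity matrix between two gene lists.

    Genes without surviving annotations in the namespace are dropped with a
    warning (they cannot be scored).
    """

    def usable(genes):
        kept, skipped = [], []
        for g in genes:
            (kept if annotations.terms_for(g, dag, namespace) else skipped).append(g)
        return kept, skipped

    rows, skipped_a = usable(genes_a)
    cols, skipped_b = usable(genes_b)
    if skipped_a or skipped_b:
        warnings.warn(
            f"dropped unannotated genes: {sorted(skipped_a + skipped_b)}",
            stacklevel=2,
        )
    data = [
        [gene_sim_bma(r, c, annotations, dag, namespace) for c in cols]
        for r in rows
    ]
    return pd.DataFrame(data, index=rows, columns=cols, dtype=float)


def cluster_semsim(
    matrix: pd.DataFrame,
    linkage: str = "average",
    n_clusters: int | None = None,
    height: float | None = 0.5,
):
    """Agglomerative clustering of a square symmetric similarity matrix.

    Works on distance = 1 - similarity. Returns ``(linkage_matrix, labels)``
    where labels is a pandas Series of flat cluster ids, cut either into
    ``n_clusters`` or at the given dendrogram ``height``.
    """
    if matrix.shape[0] != matrix.shape[1] or list(matrix.index) != list(
        matrix.columns
    ):
        raise ValueError("matrix must be square with identical row/column genes")
    sim = matrix.to_numpy(dtype=float)
    if not np.allclose(sim, sim.T, atol=1e-8):
        raise ValueError("matrix must be symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    if n_clusters is not None:
        labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        labels = hierarchy.fcluster(z, t=height, criterion="distance")
    return z, pd.Series(labels, index=matrix.index, name="cluster")
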