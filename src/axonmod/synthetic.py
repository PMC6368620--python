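"""Synthetic fixtures with the statistical structure the pipeline assumes.

Real inputs to this kind of analysis — a scored human interactome, curated
disease gene lists, the Gene Ontology, GAF annotations and GMT pathway
collections — are all large downloads. These generators produce small
stand-ins carrying the features the statistics actually exploit:

* scale-free networks (preferential attachment, power-law degree decay);
* "planted" seed sets whose induced LCC is larger than random expectation,
  with a cohesion dial controlling how strongly members cluster;
* pairs of seed sets with an exact planted overlap, grown either from a
  shared neighborhood (topologically overlapping, negative s_AB) or from
  distant network regions (separated, positive s_AB);
* toy ontologies, annotation tables and pathway collections for the
  semantic-similarity and enrichment stages.

Every generator is bit-reproducible under a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .interactome import Interactome, bfs_nearest
from .localization import SeedSet
from .semsim import AnnotationSet, GODag
from .enrichment import PathwayDB

__all__ = [
    "PlantedScenario",
    "generate_scale_free",
    "plant_module",
    "plant_overlapping_pair",
    "generate_toy_ontology",
    "generate_annotations",
    "generate_gmt",
    "hide_members",
]


@dataclass
class PlantedScenario:
    """Two planted seed sets on one graph with a known shared-member count."""

    graph: Interactome
    module_a: SeedSet
    module_b: SeedSet
    planted_overlap: int
    cohesion: float

    def __post_init__(self) -> None:
        shared = self.module_a.mapped & self.module_b.mapped
        if len(shared) != self.planted_overlap:
            raise ValueError(
                f"planted overlap {self.planted_overlap} != actual {len(shared)}"
            )


def generate_scale_free(
    n_nodes: int,
    edges_per_node: int = 3,
    rng_seed: int = 0,
    model: str = "preferential_attachment",
) -> Interactome:
    """Connected scale-free interactome stand-in.

    Preferential attachment (Barabási–Albert) by default: guaranteed
    connected, with the heavy-tailed degree distribution real interactomes
    show. ``model='configuration'`` draws a power-law degree sequence and
    keeps the largest component of the simplified configuration graph (not
    connectivity-guaranteed; kept for sensitivity checks). Edge confidences
    are drawn uniformly in [0.63, 1.0), mimicking a medium-confidence-
    filtered network.
    """
    if n_nodes < 10:
        raise ValueError("n_nodes must be >= 10")
    if edges_per_node < 1 or edges_per_node >= n_nodes:
        raise ValueError("edges_per_node must be in [1, n_nodes)")
    if model == "preferential_attachment":
        raw = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=rng_seed)
    elif model == "configuration":
        rng = np.random.default_rng(rng_seed)
        seq = np.clip(
            np.round(nx.utils.powerlaw_sequence(n_nodes, 2.5, seed=rng_seed)),
            1,
            None,
        ).astype(int)
        if seq.sum() % 2:
            seq[int(rng.integers(n_nodes))] += 1
        multi = nx.configuration_model(seq.tolist(), seed=rng_seed)
        raw = nx.Graph(multi)
        raw.remove_edges_from(nx.selfloop_edges(raw))
        largest = max(nx.connected_components(raw), key=len)
        raw = raw.subgraph(largest).copy()
    else:
        raise ValueError(f"unknown model {model!r}")
    width = len(str(n_nodes))
    relabel = {i: f"G{i:0{width}d}" for i in raw.nodes}
    g = nx.relabel_nodes(raw, relabel)
    rng = np.random.default_rng(rng_seed)
    for u, v in sorted(g.edges):
        g.edges[u, v]["confidence"] = round(float(rng.uniform(0.63, 1.0)), 3)
    return Interactome(g)


def _grow(
    adj: Mapping[str, set[str]],
    size: int,
    cohesion: float,
    rng: np.random.Generator,
    start: str | None = None,
    seed_members: Iterable[str] = (),
    forbidden: Iterable[str] = (),
    anchor: Iterable[str] | None = None,
) -> set[str]:
    """Grow a node set by cohesion-biased neighborhood sampling.

    Each new member is, with probability ``cohesion``, a uniform draw from
    the outside neighborhood of the current members (guaranteeing an
    intra-set edge) and otherwise a uniform draw over all remaining nodes.
    Cohesion 1 therefore yields a connected induced subgraph; cohesion 0 is
    plain uniform sampling. When ``anchor`` is given, the neighborhood of the
    anchor nodes is preferred over the general frontier, which keeps growth
    packed around a shared region instead of drifting away.
    """
    forbidden = set(forbidden)
    members = set(seed_members)
    anchor = set(anchor) if anchor is not None else None
    nodes = sorted(set(adj) - forbidden)
    if size > len(nodes):
        raise ValueError("cannot reach requested size: not enough nodes")
    if not members:
        if start is None:
            start = nodes[int(rng.integers(len(nodes)))]
        members.add(start)
    while len(members) < size:
        use_neighborhood = cohesion > 0 and rng.uniform() < cohesion
        picked = None
        if use_neighborhood:
            frontier: list[str] = []
            if anchor:
                frontier = sorted(
                    {
                        w
                        for m in anchor
                        for w in adj[m]
                        if w not in members and w not in forbidden
                    }
                )
            if not frontier:
                frontier = sorted(
                    {
                        w
                        for m in members
                        for w in adj[m]
                        if w not in members and w not in forbidden
                    }
                )
            if frontier:
                picked = frontier[int(rng.integers(len(frontier)))]
            elif cohesion >= 1.0:
                # frontier walled off (e.g. by a forbidden sibling module):
                # take the nearest reachable free node to stay compact
                picked = _nearest_free(adj, members, forbidden)
                if picked is None:
                    raise ValueError(
                        "cannot reach requested size by neighborhood growth"
                    )
        if picked is None:
            pool = sorted(set(nodes) - members)
            picked = pool[int(rng.integers(len(pool)))]
        members.add(picked)
    return members


def _nearest_free(
    adj: Mapping[str, set[str]], members: set[str], forbidden: set[str]
) -> str | None:
    """Closest node (BFS layers, lexicographic tie-break) outside both sets."""
    seen = set(members)
    layer = sorted(members)
    while layer:
        nxt: list[str] = []
        for u in layer:
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        free = sorted(w for w in nxt if w not in forbidden)
        if free:
            return free[0]
        layer = sorted(nxt)
    return None


def plant_module(
    g: Interactome, size: int, cohesion: float, rng_seed: int = 0
) -> SeedSet:
    """Plant one seed set with approximately the requested cohesion.

    Cohesion is the expected fraction of members adjacent to at least one
    other member (the quantity LCC statistics respond to), not edge density.
    """
    if not 0.0 <= cohesion <= 1.0:
        raise ValueError("cohesion must lie in [0, 1]")
    if size > g.n_nodes:
        raise ValueError("size exceeds node count")
    rng = np.random.default_rng(rng_seed)
    members = _grow(g.adj, size, cohesion, rng)
    ordered = tuple(sorted(members))
    return SeedSet(
        name=f"planted[size={size},cohesion={cohesion}]",
        listed=ordered,
        mapped=frozenset(ordered),
        dropped=frozenset(),
    )


def _farthest_node(adj: Mapping[str, set[str]], source: str) -> str:
    """A node at maximal hop distance from ``source`` (BFS last layer)."""
    seen = {source}
    layer = [source]
    last = source
    while layer:
        nxt = []
        for u in layer:
            for w in adj[u]:
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        if nxt:
            last = sorted(nxt)[0]
        layer = nxt
    return last


def plant_overlapping_pair(
    g: Interactome,
    size_a: int,
    size_b: int,
    overlap: int,
    cohesion: float = 1.0,
    rng_seed: int = 0,
) -> PlantedScenario:
    """Two planted modules sharing exactly ``overlap`` members.

    With overlap > 0 a shared core is grown first and both modules extend it
    from the same neighborhood (topologically overlapping). With overlap = 0
    the modules are grown around two mutually distant anchor nodes
    (topologically separated). Module memberships are kept disjoint outside
    the core so the planted overlap is exact.
    """
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed the smaller module size")
    rng = np.random.default_rng(rng_seed)
    adj = g.adj
    nodes = sorted(adj)
    if overlap > 0:
        core = _grow(adj, overlap, cohesion, rng)
        a = _grow(adj, size_a, cohesion, rng, seed_members=core, anchor=core)
        b = _grow(
            adj,
            size_b,
            cohesion,
            rng,
            seed_members=core,
            forbidden=a - core,
            anchor=core,
        )
    else:
        anchor_a = nodes[int(rng.integers(len(nodes)))]
        anchor_b = _farthest_node(adj, anchor_a)
        a = _grow(adj, size_a, cohesion, rng, start=anchor_a)
        b = _grow(adj, size_b, cohesion, rng, start=anchor_b, forbidden=a)

    def _seed_set(members: set[str], label: str) -> SeedSet:
        ordered = tuple(sorted(members))
        return SeedSet(
            name=label,
            listed=ordered,
            mapped=frozenset(ordered),
            dropped=frozenset(),
        )

    return PlantedScenario(
        graph=g,
        module_a=_seed_set(a, "planted_A"),
        module_b=_seed_set(b, "planted_B"),
        planted_overlap=overlap,
        cohesion=cohesion,
    )


def generate_toy_ontology(
    depth: int,
    branching: int,
    namespace: str = "biological_process",
    part_of_every: int | None = None,
) -> GODag:
    """Full ``branching``-ary tree ontology of the given depth.

    depth counts edge levels below the single root, so depth=3, branching=2
    gives 1 + 2 + 4 + 8 = 15 terms. Every edge is is_a unless
    ``part_of_every`` is set, in which case every k-th edge (deterministic
    enumeration order) is part_of instead.
    """
    if depth < 0 or branching < 1:
        raise ValueError("depth must be >= 0 and branching >= 1")
    n_terms = sum(branching**d for d in range(depth + 1))
    ids = [f"GO:{7000000 + i:07d}" for i in range(n_terms)]
    terms = {t: namespace for t in ids}
    edges = []
    edge_no = 0
    for i in range(1, n_terms):
        parent = ids[(i - 1) // branching]
        edge_no += 1
        rel = (
            "part_of"
            if part_of_every and edge_no % part_of_every == 0
            else "is_a"
        )
        edges.append((ids[i], parent, rel))
    return GODag(terms, edges)


_DEFAULT_EVIDENCE_MIX = {"EXP": 0.4, "IDA": 0.3, "IEA": 0.2, "IPI": 0.1}


def generate_annotations(
    genes: Iterable[str],
    dag: GODag,
    evidence_mix: Mapping[str, float] | None = None,
    terms_per_gene: tuple[int, int] = (1, 3),
    rng_seed: int = 0,
) -> AnnotationSet:
    """Random gene -> GO annotations with a controlled evidence-code mix."""
    mix = dict(evidence_mix or _DEFAULT_EVIDENCE_MIX)
    codes = sorted(mix)
    probs = np.array([mix[c] for c in codes], dtype=float)
    if probs.sum() <= 0:
        raise ValueError("evidence mix must have positive total weight")
    probs = probs / probs.sum()
    lo, hi = terms_per_gene
    if lo < 1 or hi < lo:
        raise ValueError("terms_per_gene must be a (low>=1, high>=low) pair")
    rng = np.random.default_rng(rng_seed)
    terms = sorted(dag.namespace)
    annots: dict[str, set[tuple[str, str]]] = {}
    for gene in sorted(set(genes)):
        n = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(terms), size=min(n, len(terms)), replace=False)
        pairs = set()
        for idx in sorted(chosen.tolist()):
            code = codes[int(rng.choice(len(codes), p=probs))]
            pairs.add((terms[idx], code))
        annots[gene] = pairs
    return AnnotationSet(annots)


def generate_gmt(
    n_sets: int,
    set_size: int,
    background: int | Iterable[str],
    rng_seed: int = 0,
    source: str = "synthetic",
) -> PathwayDB:
    """Random pathway collection drawn from a background universe."""
    if n_sets < 1 or set_size < 1:
        raise ValueError("n_sets and set_size must be positive")
    if isinstance(background, int):
        width = len(str(background))
        genes = [f"G{i:0{width}d}" for i in range(background)]
    else:
        genes = sorted(set(background))
    if set_size > len(genes):
        raise ValueError("set_size exceeds the background size")
    rng = np.random.default_rng(rng_seed)
    sets, desc, src = {}, {}, {}
    for i in range(n_sets):
        idx = rng.choice(len(genes), size=set_size, replace=False)
        name = f"PATHWAY_{i + 1:03d}"
        sets[name] = frozenset(genes[j] for j in idx)
        desc[name] = f"synthetic pathway {i + 1}"
        src[name] = source
    return PathwayDB(sets, desc, src)


def hide_members(
    seed_set: SeedSet, fraction: float, rng_seed: int = 0
) -> tuple[SeedSet, frozenset[str]]:
    """Split a seed set into a visible part and a hidden holdout.

    Used for module-recovery experiments: run expansion on the visible seeds
    and measure how early the hidden members are incorporated.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    members = sorted(seed_set.mapped)
    n_hide = int(round(fraction * len(members)))
    rng = np.random.default_rng(rng_seed)
    hidden_idx = set(
        rng.choice(len(members), size=n_hide, replace=False).tolist()
    )
    hidden = frozenset(members[i] for i in sorted(hidden_idx))
    visible = tuple(m for m in members if m not in hidden)
    if not visible:
        raise ValueError("hiding everything leaves no visible seeds")
    return (
        SeedSet(
            name=f"{seed_set.name}|visible",
            listed=visible,
            mapped=frozenset(visible),
            dropped=frozenset(),
        ),
        hidden,
    )
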