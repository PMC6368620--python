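"""DIAMOnD disease-module expansion.

Starting from a proto-module of seed proteins, DIAMOnD iteratively adds the
network node whose links into the current module are most statistically
surprising under a hypergeometric model: a candidate with degree k, of which
k_s point into a module of size s0 inside a network of N nodes, gets the
upper-tail probability P(X >= k_s) of drawing that many module members among
k picks. Seed weighting omega makes links to *seed* members count omega-fold
(the published weighted variant), so the expansion stays anchored to the
curated genes even as generic well-connected nodes join.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable

from .interactome import Interactome
from .localization import SeedSet, induced_lcc_size

__all__ = [
    "DiamondStep",
    "ExpandedModule",
    "connectivity_pvalue",
    "diamond_expand",
    "lcc_growth",
]


@lru_cache(maxsize=1 << 20)
def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    )


def _hypergeom_sf_log(x: int, M: int, n: int, k: int) -> float:
    """P(X >= x) for a hypergeometric(M population, n successes, k draws).

    Summed in log space so k in the thousands and p-values far below the
    float underflow of naive products remain finite.
    """
    lo = max(x, max(0, k - (M - n)))
    hi = min(n, k)
    if lo > hi:
        return 0.0
    denom = _lchoose(M, k)
    total = -math.inf
    for i in range(lo, hi + 1):
        term = _lchoose(n, i) + _lchoose(M - n, k - i) - denom
        if total == -math.inf:
            total = term
        else:
            m = max(total, term)
            total = m + math.log(math.exp(total - m) + math.exp(term - m))
    return min(1.0, math.exp(total))


def connectivity_pvalue(
    N: int, s0: int, k: int, k_s: int, omega: int = 1
) -> float:
    """Hypergeometric connectivity significance of a candidate node.

    P(X >= k_s) for k draws from a population of N containing s0 module
    members. With seed weight omega > 1, module links count omega times via
    the substitution k_s -> omega*k_s, k -> k + (omega-1)*k_s,
    s0 -> omega*s0, N -> N + (omega-1)*s0.
    """
    if k_s > k:
        raise ValueError(f"k_s ({k_s}) cannot exceed k ({k})")
    if k_s < 0 or k < 0 or s0 < 0:
        raise ValueError("counts must be non-negative")
    if omega < 1 or int(omega) != omega:
        raise ValueError("omega must be an integer >= 1")
    omega = int(omega)
    ks_w = omega * k_s
    k_w = k + (omega - 1) * k_s
    s0_w = omega * s0
    N_w = N + (omega - 1) * s0
    if ks_w == 0:
        return 1.0
    return max(_hypergeom_sf_log(ks_w, N_w, s0_w, k_w), 5e-324)


@dataclass(frozen=True)
class DiamondStep:
    """One incorporation: the chosen node with its connectivity evidence."""

    iteration: int
    node: str
    degree: int
    seed_links: int
    p_value: float

    def __post_init__(self) -> None:
        if not 1 <= self.seed_links <= self.degree:
            raise ValueError("added nodes must satisfy 1 <= k_s <= k")


@dataclass
class ExpandedModule:
    """Seeds plus the ordered DIAMOnD nodes that expand them."""

    seeds_mapped: frozenset[str]
    diamond_nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.diamond_nodes) & self.seeds_mapped:
            raise ValueError("diamond nodes must be disjoint from seeds")

    @property
    def all_members(self) -> frozenset[str]:
        return self.seeds_mapped | frozenset(self.diamond_nodes)

    @property
    def provenance(self) -> dict[str, str]:
        out = {s: "seed" for s in self.seeds_mapped}
        out.update(
            {n: f"diamond:{i}" for i, n in enumerate(self.diamond_nodes, 1)}
        )
        return out


def _weighted_pvalue(
    N: int,
    n_seeds: int,
    n_added: int,
    k: int,
    ks_seed: int,
    ks_added: int,
    omega: int,
    memo: dict,
) -> float:
    """Published weighted variant: only links to seeds count omega-fold."""
    kb = omega * ks_seed + ks_added
    kk = k + (omega - 1) * ks_seed
    ss = omega * n_seeds + n_added
    NN = N + (omega - 1) * n_seeds
    key = (kk, kb)
    p = memo.get(key)
    if p is None:
        p = _hypergeom_sf_log(kb, NN, ss, kk) if kb > 0 else 1.0
        memo[key] = p
    return p


def diamond_expand(
    g: Interactome,
    seed_set: SeedSet | Iterable[str],
    n_iter: int = 200,
    omega: int = 10,
    tie_rule: str = "deterministic",
) -> tuple[list[DiamondStep], ExpandedModule]:
    """Run DIAMOnD for ``n_iter`` iterations from a mapped seed set.

    At every iteration the candidates are the non-member nodes adjacent to
    at least one module member; the candidate with the smallest connectivity
    p-value joins. Ties are broken deterministically (higher k_s, then lower
    k, then lexicographic identifier); ``tie_rule='insertion'`` instead keeps
    the earliest-discovered candidate, mimicking implementations whose
    results depend on dict insertion order.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if tie_rule not in {"deterministic", "insertion"}:
        raise ValueError(f"unknown tie rule {tie_rule!r}")
    seeds = (
        set(seed_set.mapped) if isinstance(seed_set, SeedSet) else set(seed_set)
    )
    if not seeds:
        raise ValueError("seed set maps to no network nodes")
    missing = seeds - set(g.adj)
    if missing:
        raise KeyError(f"seeds not in the interactome: {sorted(missing)}")
    adj = g.adj
    N = g.n_nodes
    module = set(seeds)
    added: list[str] = []
    steps: list[DiamondStep] = []

    # candidate -> [links to seeds, links to added nodes]; insertion order of
    # this dict is the discovery order used by tie_rule='insertion'
    cand: dict[str, list[int]] = {}
    for s in sorted(seeds):
        for w in sorted(adj[s]):
            if w in module:
                continue
            entry = cand.get(w)
            if entry is None:
                cand[w] = [1, 0]
            else:
                entry[0] += 1

    if not cand:
        raise ValueError("no candidate is adjacent to the seed set")

    for it in range(1, n_iter + 1):
        if not cand:
            warnings.warn(
                f"candidates exhausted after {it - 1} iterations", stacklevel=2
            )
            break
        memo: dict = {}
        best = None
        best_key = None
        for idx, (node, (ks_seed, ks_added)) in enumerate(cand.items()):
            k = len(adj[node])
            p = _weighted_pvalue(
                N, len(seeds), len(added), k, ks_seed, ks_added, omega, memo
            )
            ks = ks_seed + ks_added
            if tie_rule == "deterministic":
                key = (p, -ks, k, node)
            else:
                key = (p, idx)
            if best_key is None or key < best_key:
                best_key = key
                best = (node, k, ks, p)
        node, k, ks, p = best
        steps.append(
            DiamondStep(
                iteration=it, node=node, degree=k, seed_links=ks, p_value=p
            )
        )
        module.add(node)
        added.append(node)
        del cand[node]
        for w in sorted(adj[node]):
            if w in module:
                continue
            entry = cand.get(w)
            if entry is None:
                cand[w] = [0, 1]
            else:
                entry[1] += 1

    return steps, ExpandedModule(
        seeds_mapped=frozenset(seeds), diamond_nodes=tuple(added)
    )


def lcc_growth(g: Interactome, expanded: ExpandedModule) -> int:
    """How much the module's LCC grows when DIAMOnD nodes are included."""
    full = induced_lcc_size(g.adj, set(expanded.all_members))
    seeds_only = induced_lcc_size(g.adj, set(expanded.seeds_mapped))
    return full - seeds_only
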