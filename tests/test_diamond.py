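import itertools
import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from axonmod import (
    build_graph,
    connectivity_pvalue,
    diamond_expand,
    lcc_growth,
    plant_module,
)
from axonmod.diamond import ExpandedModule, _weighted_pvalue
from axonmod.interactome import Interactome, InteractionRecord


def enumeration_pvalue(N, s0, k, k_s):
    """Brute force P(X >= k_s): enumerate all k-subsets of the population."""
    hits = total = 0
    for draw in itertools.combinations(range(N), k):
        total += 1
        hits += sum(1 for i in draw if i < s0) >= k_s
    return hits / total


class TestConnectivityPvalue:
    def test_zero_links_is_certain(self):
        assert connectivity_pvalue(100, 10, 5, 0) == 1.0

    def test_worked_example_three_over_fortyfive(self):
        p = connectivity_pvalue(10, 3, 2, 2, omega=1)
        assert p == pytest.approx(3 / 45, rel=1e-12)

    def test_matches_subset_enumeration(self):
        for N, s0, k, ks in [
            (8, 3, 3, 2),
            (10, 3, 2, 2),
            (12, 5, 4, 1),
            (12, 4, 3, 3),
            (9, 2, 5, 1),
        ]:
            assert connectivity_pvalue(N, s0, k, ks) == pytest.approx(
                enumeration_pvalue(N, s0, k, ks), rel=1e-9
            )

    def test_matches_scipy_tail_on_grid(self):
        for N in (50, 500, 5000):
            for s0 in (5, 40):
                for k in (3, 45):
                    for ks in range(0, min(k, s0) + 1, 7):
                        mine = connectivity_pvalue(N, s0, k, ks)
                        ref = stats.hypergeom.sf(ks - 1, N, s0, k)
                        assert mine == pytest.approx(ref, rel=1e-8, abs=1e-300)

    def test_seed_weight_strictly_sharpens_significance(self):
        for N, s0, k, ks in [(100, 10, 5, 1), (100, 10, 5, 3), (500, 20, 8, 2)]:
            assert connectivity_pvalue(N, s0, k, ks, omega=10) < (
                connectivity_pvalue(N, s0, k, ks, omega=1)
            )

    def test_weighting_is_the_stated_substitution(self):
        omega = 10
        for N, s0, k, ks in [(100, 10, 5, 2), (300, 12, 7, 3)]:
            direct = connectivity_pvalue(N, s0, k, ks, omega=omega)
            substituted = connectivity_pvalue(
                N + (omega - 1) * s0,
                omega * s0,
                k + (omega - 1) * ks,
                omega * ks,
                omega=1,
            )
            assert direct == pytest.approx(substituted, rel=1e-12)

    def test_survives_huge_degrees(self):
        p = connectivity_pvalue(20000, 300, 4000, 900, omega=10)
        assert 0 < p <= 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            connectivity_pvalue(10, 3, 2, 3)
        with pytest.raises(ValueError):
            connectivity_pvalue(10, 3, 2, 1, omega=0)


def _first_pick_oracle(g, seeds, omega=1):
    """argmin over candidates of the enumeration p-value (graphs <= 12 nodes)."""
    best = None
    for node in sorted(g.nodes):
        if node in seeds:
            continue
        k = g.degree(node)
        ks = len(g.adj[node] & seeds)
        if ks == 0:
            continue
        N = g.n_nodes + (omega - 1) * len(seeds)
        p = enumeration_pvalue(
            N, omega * len(seeds), k + (omega - 1) * ks, omega * ks
        )
        if best is None or p < best[0] - 1e-12:
            best = (p, node)
    return best


class TestDiamondExpand:
    def test_star_center_seed_adds_one_leaf(self):
        g = build_graph(
            [InteractionRecord("hub", f"leaf{i}", 0.9) for i in range(4)]
        )
        steps, expanded = diamond_expand(g, {"hub"}, n_iter=1, omega=1)
        assert len(steps) == 1
        assert steps[0].seed_links == 1
        assert steps[0].node.startswith("leaf")
        assert len(expanded.all_members) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_first_pick_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        raw = nx.gnp_random_graph(n, 0.35, seed=seed)
        raw.add_edges_from((i, i + 1) for i in range(n - 1))
        nx.set_edge_attributes(raw, 1.0, "confidence")
        g = Interactome(nx.relabel_nodes(raw, {i: f"n{i:02d}" for i in raw}))
        nodes = sorted(g.nodes)
        seeds = set(nodes[: int(rng.integers(2, 4))])
        steps, _ = diamond_expand(g, seeds, n_iter=1, omega=1)
        oracle_p, _ = _first_pick_oracle(g, seeds, omega=1)
        chosen = steps[0]
        N, k = g.n_nodes, chosen.degree
        assert enumeration_pvalue(
            N, len(seeds), k, chosen.seed_links
        ) == pytest.approx(oracle_p, rel=1e-9)

    def test_incremental_bookkeeping_equals_full_recomputation(self, ba500):
        seeds = plant_module(ba500, 8, 1.0, rng_seed=2).mapped
        steps, _ = diamond_expand(ba500, seeds, n_iter=15, omega=10)

        # naive reference: recompute every candidate from raw adjacency
        module = set(seeds)
        for step in steps:
            best = None
            for node in sorted(ba500.adj):
                if node in module:
                    continue
                nbrs = ba500.adj[node]
                ks_seed = len(nbrs & seeds)
                ks_added = len(nbrs & module) - ks_seed
                if ks_seed + ks_added == 0:
                    continue
                p = _weighted_pvalue(
                    ba500.n_nodes,
                    len(seeds),
                    len(module) - len(seeds),
                    len(nbrs),
                    ks_seed,
                    ks_added,
                    10,
                    {},
                )
                key = (p, -(ks_seed + ks_added), len(nbrs), node)
                if best is None or key < best[0]:
                    best = (key, node, p)
            assert best[1] == step.node
            assert best[2] == pytest.approx(step.p_value, rel=1e-9)
            module.add(step.node)

    def test_every_added_node_touches_the_module(self, ba500):
        seeds = plant_module(ba500, 10, 1.0, rng_seed=3)
        steps, expanded = diamond_expand(ba500, seeds, n_iter=40, omega=10)
        assert [s.iteration for s in steps] == list(range(1, 41))
        for s in steps:
            assert 1 <= s.seed_links <= s.degree
            assert 0 < s.p_value <= 1
        assert len(expanded.all_members) == 50
        assert not set(expanded.diamond_nodes) & expanded.seeds_mapped

    def test_candidate_exhaustion_warns_and_stops(self):
        g = build_graph(
            [
                InteractionRecord("a", "b", 0.9),
                InteractionRecord("x", "y", 0.9),
            ]
        )
        with pytest.warns(UserWarning, match="exhausted"):
            steps, _ = diamond_expand(g, {"a"}, n_iter=5, omega=1)
        assert len(steps) == 1  # only b is ever reachable

    def test_isolated_seed_errors(self, path5):
        g = build_graph(
            [
                InteractionRecord("a", "b", 0.9),
                InteractionRecord("x", "y", 0.9),
            ]
        )
        with pytest.raises(ValueError, match="no candidate"):
            diamond_expand(g, {"a", "b"}, n_iter=1)

    def test_insertion_order_tie_mode_runs(self, ba500):
        seeds = plant_module(ba500, 8, 1.0, rng_seed=4)
        steps, _ = diamond_expand(
            ba500, seeds, n_iter=10, omega=10, tie_rule="insertion"
        )
        assert len(steps) == 10


class TestLccGrowth:
    def test_no_diamond_nodes_no_growth(self, ba500):
        seeds = plant_module(ba500, 10, 1.0, rng_seed=1)
        expanded = ExpandedModule(
            seeds_mapped=frozenset(seeds.mapped), diamond_nodes=()
        )
        assert lcc_growth(ba500, expanded) == 0

    def test_bridge_node_joins_fragments(self):
        # two triangles joined only through a bridge node
        tri1 = [("a", "b"), ("b", "c"), ("a", "c")]
        tri2 = [("x", "y"), ("y", "z"), ("x", "z")]
        bridge = [("c", "m"), ("m", "x")]
        g = build_graph(
            [InteractionRecord(u, v, 0.9) for u, v in tri1 + tri2 + bridge]
        )
        expanded = ExpandedModule(
            seeds_mapped=frozenset("abcxyz"), diamond_nodes=("m",)
        )
        growth = lcc_growth(g, expanded)
        assert growth >= 3 + 1  # smaller fragment plus the bridge itself
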