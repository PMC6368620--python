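"""Null-model node sampling: uniform and degree-binned.

Degree-binned sampling draws, for every node of an observed set, a random
node from the same logarithmic degree bin, which controls the hub bias of
uniform sampling (high-degree nodes inflate connectivity statistics).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["DegreeBins", "sample_uniform", "sample_degree_matched"]


def sample_uniform(
    nodes: Sequence[str], size: int, rng: np.random.Generator
) -> list[str]:
    idx = rng.choice(len(nodes), size=size, replace=False)
    return [nodes[i] for i in idx]


class DegreeBins:
    """Nodes partitioned into log2-width degree bins.

    Bins with fewer than ``min_bin_size`` nodes are merged upward into the
    next bin so every bin is large enough to sample from.
    """

    def __init__(self, degrees: dict[str, int], min_bin_size: int = 50):
        by_bin: dict[int, list[str]] = {}
        for node, deg in degrees.items():
            b = int(math.log2(deg)) if deg > 0 else -1
            by_bin.setdefault(b, []).append(node)
        # merge sparse bins upward (highest-degree bin absorbs leftovers down)
        keys = sorted(by_bin)
        merged: list[list[str]] = []
        bounds: list[int] = []
        carry: list[str] = []
        for b in keys:
            carry.extend(by_bin[b])
            if len(carry) >= min_bin_size:
                merged.append(sorted(carry))
                bounds.append(b)
                carry = []
        if carry:
            if merged:
                merged[-1] = sorted(merged[-1] + carry)
            else:
                merged.append(sorted(carry))
                bounds.append(keys[-1])
        self._bins = merged
        self._bounds = bounds
        self._node_bin: dict[str, int] = {}
        for i, members in enumerate(merged):
            for n in members:
                self._node_bin[n] = i

    def bin_of(self, node: str) -> int:
        return self._node_bin[node]

    def sample_like(
        self, template: Sequence[str], rng: np.random.Generator
    ) -> list[str]:
        """Random node set matching the template's degree-bin profile.

        Sampling is without replacement across the whole drawn set
        (rejection within bins).
        """
        chosen: set[str] = set()
        out: list[str] = []
        for node in template:
            pool = self._bins[self._node_bin[node]]
            for _ in range(10 * len(pool)):
                cand = pool[int(rng.integers(len(pool)))]
                if cand not in chosen:
                    break
            else:  # bin exhausted; fall back to any unused node
                rest = [n for n in self._node_bin if n not in chosen]
                cand = rest[int(rng.integers(len(rest)))]
            chosen.add(cand)
            out.append(cand)
        return out


def sample_degree_matched(
    bins: DegreeBins,
    template: Sequence[str],
    rng: np.random.Generator,
) -> list[str]:
    return bins.sample_like(template, rng)
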