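import pytest

from axonmod import build_graph, generate_scale_free
from axonmod.interactome import InteractionRecord
from axonmod.semsim import GODag


@pytest.fixture(scope="session")
def path5():
    """The 5-node path a-b-c-d-e used by the hand-computed examples."""
    pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
    return build_graph([InteractionRecord(u, v, 0.9) for u, v in pairs])


@pytest.fixture(scope="session")
def ba500():
    """Small preferential-attachment graph for unit-scale experiments."""
    return generate_scale_free(500, 2, rng_seed=11)


@pytest.fixture(scope="session")
def ba2000():
    """Study-scale synthetic interactome: 2000 nodes, 3 edges per new node."""
    g = generate_scale_free(2000, 3, rng_seed=0)
    g.adj  # warm the adjacency cache once per session
    return g


@pytest.fixture(scope="session")
def chain_dag():
    """Three-term is_a chain G -> C -> R (leaf, parent, root)."""
    ns = "biological_process"
    return GODag(
        {"G": ns, "C": ns, "R": ns},
        [("G", "C", "is_a"), ("C", "R", "is_a")],
    )
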