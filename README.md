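# axonmod

Network-medicine analysis of disease gene modules on protein–protein
interaction (PPI) networks.

Genetically heterogeneous Mendelian disorders — the motivating case is the
inherited axonopathies, axonal Charcot-Marie-Tooth disease (CMT2) and
hereditary spastic paraplegia (HSP) — have dozens of causal genes each.
Network medicine exploits the observation that disease proteins cluster into
"modules" of the interactome. `axonmod` implements the full analysis chain a
systems-biology group runs on such gene lists:

1. **Interactome construction** — parse a HIPPIE-style scored interaction
   table, keep interactions with confidence ≥ 0.63 (medium confidence), build
   an undirected simple graph.
2. **Proto-module localization** — for a seed gene set *S*, the size of the
   largest connected component (LCC) of the induced subgraph, with a z-score
   against 10,000 random same-size sets, and the per-seed nearest-seed
   shortest distance *d_s* tested by a one-sided Mann-Whitney U against a
   pooled randomization null. A set with *z* ≥ 1.6 and *p* ≤ 0.05 is a
   proto-module.
3. **Module separation** — for two seed sets,
   *s*<sub>AB</sub> = *d*<sub>AB</sub> − (*d*<sub>AA</sub> + *d*<sub>BB</sub>)/2,
   with a z-score against random (degree-matched by default) set pairs;
   *z* ≤ −1.6 means topologically overlapping modules, *z* ≥ 1.6 separated.
4. **DIAMOnD expansion** — iteratively add the node whose links into the
   module are most significant under a hypergeometric model
   *P*(*X* ≥ *k*<sub>s</sub>), with seed links weighted ω = 10, for 200
   iterations.
5. **Semantic-similarity validation** — Wang graph-based GO term similarity
   (is_a 0.8, part_of 0.6) combined per gene pair by the best-match average
   (BMA), after removing IEA/IPI evidence codes; hierarchical clustering of
   the similarity matrix.
6. **Pathway over-representation** — hypergeometric ORA of the six derived
   module sets (each module, intersection "core", union "spectrum", both
   differences) against GMT collections, Benjamini-Hochberg FDR ≤ 0.2,
   Jaccard (> 0.1) grouping of significant pathways, and dominance
   assignment per pathway.

A `synthetic` module generates scale-free interactomes, planted disease
modules with controllable cohesion and pairwise overlap, toy ontologies,
annotations and pathway collections, so the entire pipeline runs and is
tested without any downloads.

## Worked example

```python
from axonmod import (
    generate_scale_free, plant_module, plant_overlapping_pair,
    lcc_significance, proximity_significance, separation_significance,
)

g = generate_scale_free(2000, 3, rng_seed=0)

seeds = plant_module(g, 30, 1.0, rng_seed=1)          # a cohesive module
lcc = lcc_significance(g, seeds, n_rand=1000, rng_seed=2)
prox = proximity_significance(g, seeds, n_rand=300, rng_seed=3)

sc = plant_overlapping_pair(g, 30, 30, 15, 1.0, rng_seed=4)
sep = separation_significance(g, sc.module_a, sc.module_b,
                              n_rand=300, rng_seed=5)
```

Running `examples/02_proto_module_localization.py` and
`examples/03_module_separation.py` (which execute exactly this) prints:

```
cohesive (disease-like) seed set:
  LCC size S = 30 (null 1.89 +/- 0.83), z = 33.7, p = 0.000999, proto-module: True
  mean nearest-seed distance = 1.00 (null mean 2.28), Mann-Whitney p = 3.2e-22
random seed set:
  LCC size S = 3 (null 1.89 +/- 0.83), z = 1.3, p = 0.1469, proto-module: False

shared-etiology pair (planted overlap = 15):
  d_AA = 1.00, d_BB = 1.00, d_AB = 0.50 -> s_AB = -0.500
  z = -3.46, p = 0.00055 -> overlapping; 18 direct cross edges
unrelated pair (planted overlap = 0):
  d_AA = 1.00, d_BB = 1.00, d_AB = 2.05 -> s_AB = 1.050
  z = 8.37, p = 5.62e-17 -> separated; 5 direct cross edges
```

The cohesive set's 30-member LCC sits 34 standard deviations above the
random expectation of ~1.9 — a proto-module — while the random set does not
deviate from its null. The pair sharing half its members gets a negative
separation (*s*<sub>AB</sub> = −0.5, overlapping); the pair planted in
distant network regions a positive one (separated). The other examples in
`examples/` walk through interactome parsing, DIAMOnD recovery of hidden
module members, semantic-similarity validation, and six-set pathway
enrichment.

A thin CLI mirrors the library for shell pipelines:

```bash
axonmod simulate --nodes 2000 --m 3 --module-size 30 --overlap 10 --seed 42 --out-dir fixtures/
axonmod proto-module --edges fixtures/edges.tsv --seeds fixtures/seeds_a.txt --n-rand 1000 --rng 1 --out proto.json
axonmod separation --edges fixtures/edges.tsv --seeds-a fixtures/seeds_a.txt --seeds-b fixtures/seeds_b.txt --out sep.json
axonmod diamond --edges fixtures/edges.tsv --seeds fixtures/seeds_a.txt --iterations 200 --omega 10 --out diamond.tsv
```

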