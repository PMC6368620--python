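# Methods

This note documents the statistical models implemented in `axonmod`, the
parameters that matter, the synthetic data the tests run on, and the design
choices made where conventions genuinely diverge.

## Interactome

The interactome is an undirected simple graph built from a scored
interaction table (HIPPIE-style TSV: name A, Entrez A, name B, Entrez B,
confidence in [0, 1], annotation). Filtering keeps confidence ≥ threshold
(inclusive; the conventional cutoffs are 0.63 for medium and 0.73 for high
confidence). Self-loops are dropped; duplicate pairs collapse to the maximum
confidence, on the view that the best-supported evidence wins. Identifiers
resolve to the Entrez id when present, otherwise to the gene symbol before
`_HUMAN`; an explicit two-column mapping overrides both, because curated
seed lists usually carry symbols while interaction tables carry both.
Ambiguous symbols are never guessed: unmapped seeds are reported in
`SeedSet.dropped`.

The graph is used as-is, not restricted to its largest component. All
distances are unweighted hop counts; a source that cannot reach any target
is reported as infinite and excluded from means downstream, never silently
dropped (`n_excluded_unreachable` carries the count).

## Localization statistics

For a mapped seed set *S* on graph *G*:

* **LCC size** — the size of the largest connected component of the
  subgraph induced by *S*. The null draws `n_rand` node sets of size |S|
  uniformly over all nodes (matching the original randomization scheme); a
  degree-binned variant is available behind `sampling="degree_binned"` for
  sensitivity analysis, since hubs inflate LCCs. Reported:
  z = (S − mean)/sd, and an add-one empirical p = (r + 1)/(n + 1) where r
  counts null values ≥ observed (avoids p = 0 at finite n). A set is a
  proto-module when z ≥ 1.6 and p ≤ 0.05.
* **Randomized p-value** — LCC size is a small integer, so the add-one p is
  discrete and conservative: its distribution under the null steps far from
  uniform. `LCCResult.p_randomized` implements the standard randomized
  p-value for discrete statistics, P(null > S) + U·P(null = S) with
  U ~ Uniform(0,1) drawn from the same seeded generator. It is exactly
  uniform under the null and is what the calibration test checks; the
  add-one p remains the headline number because it is the reproducible,
  conservative report.
* **Seed distances** — for each seed, the hop distance to the nearest other
  seed. Significance pools every finite nearest-neighbor distance from
  `n_rand` random same-size sets and applies a one-sided Mann-Whitney U
  (observed stochastically smaller), exact for small combined samples
  without ties, otherwise the tie-corrected normal approximation. Whether
  the null should be pooled distances or per-randomization means is a
  judgment call; pooling is the default and `null_mode="means"` provides the
  alternative.

Defaults: `n_rand=10000` (library), reduced in tests and the acceptance
script to 100–1,000 since z-scores of the planted effects here are an order
of magnitude beyond the 1.6 threshold and do not need that resolution.

## Separation

s_AB = d_AB − (d_AA + d_BB)/2, where d_AA/d_BB are mean nearest-other-member
distances within each set and d_AB is the mean, over members of both sets,
of the distance to the nearest member of the other set (a shared member
contributes 0). Negative s_AB ⇒ overlapping neighborhoods. The null draws
`n_rand` random set pairs of the observed sizes; the default sampling is
**degree-binned** (log₂-width degree bins merged upward until each holds at
least 50 nodes, sampling within the bin of each observed member) because
uniform sampling lets hub-heavy observed sets look artificially close;
uniform sampling is available via a flag. The p-value is the two-sided
normal tail of the z-score (the separation null is approximately Gaussian);
classification: overlapping (z ≤ −1.6, p ≤ 0.05), separated (z ≥ 1.6,
p ≤ 0.05), else unclear.

Cross-edge counting between two sets uses a documented, stable convention:
edges with one endpoint in A\B and the other in B\A, plus edges inside
A∩B, each once. Edges touching a shared node from one side only are not
counted; other conventions exist, and this one is chosen for its symmetry
and assertable algebra (A = B reduces to the intra-set edge count).

## DIAMOnD expansion

At each iteration the candidates are the non-member nodes adjacent to ≥ 1
module member. A candidate with degree k and k_s links into the current
module of size s0 in a network of N nodes scores the hypergeometric upper
tail P(X ≥ k_s) for k draws from a population of N containing s0 successes.
Seed weighting ω (default 10, the published recommendation) counts links to
*seed* members ω-fold: k_s → ω·k_s(seed) + k_s(added), k → k + (ω−1)·k_s(seed),
s0 → ω·|seeds| + |added|, N → N + (ω−1)·|seeds|. The generic primitive
`connectivity_pvalue` applies the uniform substitution to all of
(k_s, k, s0, N), which reduces to the same expression when the module is
seeds-only. The tail sum runs in log space (lgamma-based log-binomials with
log-sum-exp), so degrees in the thousands and p-values below the float
underflow of naive products remain finite.

Tie-breaking at equal p is deterministic: higher k_s, then lower k, then
lexicographic identifier. The published algorithm leaves tie order to dict
iteration, so `tie_rule="insertion"` reproduces discovery-order behavior
when matching an external run matters. Candidate link counts are maintained
incrementally as nodes join; a property test pins the contract that this is
identical to full recomputation. The run executes exactly `n_iter`
iterations (default 200) unless candidates are exhausted, which warns and
stops.

## Semantic similarity

Wang S-values: S(term) = 1; for an ancestor t within the term's closure,
S(t) = max over children t′ of w(relation) · S(t′), with w(is_a) = 0.8 and
w(part_of) = 0.6 (the method's standard weights). Other relation types
(e.g. regulates) are ignored with a count when loading OBO files. Term
similarity is the shared S-mass ratio; gene similarity is the best-match
average of the term-pair matrix, computed on biological_process annotations
by default. IEA (electronic) and IPI (physical-interaction) evidence codes
are excluded before scoring — IPI specifically because validating proteins
that came *from* a physical-interaction network with IPI-derived
annotations would be circular. Genes annotated only by excluded codes are
flagged and dropped from matrices with a warning, never scored as zero.

Hierarchical clustering runs on distance 1 − similarity with a configurable
linkage (default average); the flat-cluster cut (count or height) is a user
parameter because no single convention is canonical.

## Enrichment

ORA: for pathway of size K in background B with query Q and overlap m,
p = P(X ≥ m) (hypergeometric); enrichment ratio = (m/|Q|)/(K/B);
Benjamini-Hochberg step-up FDR across all tested pathways, with the
significance cut FDR ≤ 0.2 (inclusive). The background defaults to the
interactome's gene set, not the genome: queries are interactome-derived, so
a genomic background would inflate significance. Pathways are harmonized to
the background before testing; significant pathways are grouped into
connected components of the Jaccard graph (J strictly > 0.1).

Dominance assignment over the six module sets (module A, module B, core,
spectrum, A-only, B-only) follows a complete decision table: significant in
A-only but not B-only ⇒ A-dominant (and mirrored); any other combination
that is significant somewhere ⇒ shared (AXONO); significant nowhere ⇒
excluded. The both-differences-significant case is assigned to the shared
category by completion — it is an interpretation, flagged as such in the
docstring.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
the biology: preferential-attachment graphs (guaranteed connected, power-law
degree decay; a configuration-model variant exists behind a flag) with the
study-scale default of 2,000 nodes and 3 edges per new node; planted modules
grown by cohesion-biased neighborhood sampling, where cohesion is the
expected fraction of members adjacent to another member (the quantity LCC
statistics respond to), so cohesion 1 gives a connected module and cohesion
0 is a uniform random set; planted pairs share an exactly-sized core and
grow both remainders from the core's neighborhood (overlap > 0) or around
two mutually distant anchors (overlap = 0). When a module's growth frontier
is walled off by its sibling, growth falls back to the nearest reachable
free node, keeping the set compact while preserving the exact overlap.
Ontologies are full b-ary trees; annotations draw terms uniformly with a
configurable evidence-code mix; pathway collections are uniform draws from
the background.

What passing tests on these fixtures shows: the statistics recover planted
topology (connectivity, overlap sign and classification, hidden members)
and are calibrated under their own nulls. What it does not show: behavior
under the degree correlations, ascertainment bias and annotation structure
of real interactomes and real GO — scale-free topology is emulated, the
rest is not.

## Problem sizes and numerics

Tests and the acceptance script use a 2,000-node graph, 30-member modules,
100–1,000 randomizations per null, 100 expansion iterations and 20–50
replicates per recovery experiment; these sizes put the planted effects far
outside their nulls while keeping every run deterministic under its seed.
Empirical p-values use the add-one rule; hypergeometric tails are exact in
log space (no normal approximation); the Mann-Whitney normal approximation
applies tie correction; degenerate nulls (sd = 0) report z as undefined
rather than dividing by zero, and classification then falls back to
"unclear" / non-significant. All generators and statistics are
bit-reproducible given `rng_seed`.

## Known limitations

* Distances are unweighted hops; confidence scores filter edges but do not
  weight paths.
* The separation null assumes approximate normality of s_AB over random
  pairs for its analytic p-value.
* Exact replication of a third-party expansion run can require the
  insertion-order tie mode, since published implementations do not fix tie
  order.
* Real-data headline quantities (module sizes of specific diseases)
  additionally depend on the interaction database release and curated seed
  lists, which are not bundled.
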