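# Methods

## The model of tissue organization

A region of spatially resolved omics data (CODEX, MIBI-TOF, STARmap
PLUS, Xenium, ...) is reduced to a *cellular community* (CC): the
Delaunay triangulation of the cell centroids, with each node labeled by
its annotated cell type.  Edges are taken as hypothetical spatial
adjacencies.  The unit of multicellular organization is the *CC motif*:
a small connected labeled graph that recurs within the community as an
**induced** subgraph — non-edges must match, so a triangle motif is not
matched by an open path of the same types.

Two occurrence conventions are implemented and always kept distinct:

* **embedding census** `count_embeddings(G, m)` — the number of distinct
  vertex subsets of `G` inducing `m`; for sizes 1–3 this is computed by
  direct enumeration of typed nodes, edges and triangles
  (`census_small`), and for general sizes by VF2 search;
* **node-centric presence sum** `F(G, m) = Σ_v f(g_{v,hop}, m)` — the
  number of cells whose `hop`-neighborhood *enclosed graph* contains the
  motif.  `f` is either the exact matcher ("oracle" mode) or the learned
  presence classifier.  `F ≤ n` by construction.

`hop = 2` everywhere by default, keeping enclosed graphs comparable in
size to the motifs; a helper suggests `⌈diam(m)/2⌉` but is never applied
silently.

## The presence classifier

`SubgraphPresenceClassifier` decides whether a query motif occurs inside
a small target graph.  Both graphs pass through a shared GIN-style
encoder: per layer

    h_v ← MLP( (1+ε) h_v + Σ_{u∈N(v)} h_u + a·PE_v ),

where `PE_v` is the unweighted shortest-path distance from an anchor
node `v0` — an endpoint of a maximum-length shortest path (a diameter
endpoint, ties broken by smallest node index) — broadcast across hidden
channels and scaled by `a`.  Node features start as one-hot cell types.
Each MLP is two linear maps with leaky rectifiers and one per-node layer
normalization after the first map; layer normalization (rather than
batch statistics) keeps inference deterministic per sample and prevents
the activation growth that sum aggregation over triangulation degrees
(~6) otherwise causes, while the leaky slope removes the dead-rectifier
basin that plain rectifiers fall into on this task.
The query motif is summarized by coordinate-wise max pooling over its
final node embeddings concatenated with mean pooling, projected to
hidden width.  The head then scores every *target node* against the
motif vector — concatenation with elementwise product and squared
difference through a small MLP — and aggregates the per-node match
scores with a masked log-sum-exp, a smooth version of "some
neighborhood matches", before the sigmoid.  This node-wise matching
head mirrors the presence semantics directly; comparing globally
pooled vectors of both graphs (the simpler alternative) trained more
slowly and less accurately, and interaction features (product, squared
difference) were essential in either variant.

Training minimizes binary cross-entropy with Adam (decoupled weight
decay, global-norm gradient clipping, multiplicative learning-rate
decay), all in numpy with hand-derived gradients; fitting and inference
run under a single BLAS thread so a fixed `random_state` gives bitwise
identical results regardless of machine load.  Prediction averages the
probabilities of the best `n_checkpoints` validation-MCC epoch
checkpoints, optionally pooled over `n_restarts` independently seeded
training runs — a cheap ensemble that reliably beats the single best
checkpoint on this task.  Setting `a = 0` exactly reproduces a
plain-GIN model (a wiring regression test asserts this), and `ε` is a
fixed scalar, 0 by default.

Defaults: 3 layers, hidden width 64, `a = 0.5`, learning rate 1e-3
decayed by 0.985 per epoch, 100 epochs, batch 64, weight decay 1e-4,
head dropout 0.3, threshold 0.5.  The width/depth/rate values are
desk-scale choices recorded in the estimator's parameters and selected
on validation MCC; the positional term must not dominate the one-hot
label features in early layers (very large `a` destabilizes training,
`a = 0` measurably hurts the node-wise match).

## Synthetic benchmark

The generator mirrors the benchmark regime the classifier is meant for:

* targets are Delaunay triangulations of `n` uniform random points in
  the unit square with i.i.d. uniform cell-type labels (no spatial
  autocorrelation — real tissue is clumpier, so passing benchmarks here
  does not certify performance on structured tissue);
* motif topologies are sampled directly out of random triangulations
  (guaranteeing realizability) and deduplicated by canonical form; the
  size-3 set always includes the triangle; one topology per size in the
  default spec, sizes 3–9;
* each topology is decorated with label permutations sampled without
  replacement with respect to label-isomorphism; a registry of used
  permutations lets an independent test set be provably disjoint;
* positives are generated by *planting* (relabeling an embedding of the
  topology in a fresh random graph), negatives by rejection sampling
  (regenerate until the motif is absent, retry budget 200); every label
  is re-verified by the exact matcher before a pair is emitted; classes
  are balanced 1:1 and split 8:1:1 stratified by motif size and label.

Default corpus shape: 8/16/32 node types, 16/32-node targets for motif
sizes 3–6 and 32/64 for 7–9, 50 permutations per topology and 1000
targets per permutation.  The desk-scale fixture corpus used by the test
suite and the acceptance script keeps the regime (sizes 3–5, 8 types,
16–32-node targets) at reduced counts: one labeled motif per size and
1,600 targets per motif, ~4,800 pairs — at desk scale, target-graph
diversity per motif matters far more for generalization than motif
diversity, so the pair budget is spent on graphs.

## Pattern growth

Sizes 1–3 are enumerated exhaustively (typed nodes, edges and triangles
— triangles only at size 3, because motifs live in triangulations).
The growth step attaches one new typed node that closes a triangle on an
existing edge of the seed (pendant single-edge attachment is available
behind a flag); candidates are canonical-deduplicated.  Selection is by
plain summed occurrence, or, in a case/control design, by the
differential score: a two-sided Fisher exact test on the 2×2 table

    [occurrences, eligible sites − occurrences] × condition,

with eligible sites = Σ nodes for the presence-sum convention and
Σ edges / Σ triangles for census counts (the margin construction is
recorded in output metadata).  `-log10 p` is the default score; Cramér's
V of the same table is the alternative.  Ties always break by the
lexicographically smallest canonical string, making growth
deterministic.  A full per-size trace (candidates, scores, winner) is
retained for audit.

The exact node-centric counter caches the enclosed-graph decomposition
per graph and answers census-shaped motifs (typed node / edge /
triangle) from precomputed per-neighborhood summaries; for larger motifs
it first requires every labeled triangle of the motif to occur in the
neighborhood's triangle summary (a restriction of any induced occurrence)
before running VF2.  Both shortcuts are exactness-preserving.

## Statistics

* Fisher's exact test (two-sided, hypergeometric); Bonferroni and
  Benjamini–Hochberg adjustment.
* Cramér's V `ES = sqrt(χ² / (n·(k−1)))`, χ² without continuity
  correction (configurable); `ES ≥ 0.21` marks a moderate effect.
* Triangle (size-3) conditional effect size: fixing each type `C` of a
  triple in turn, the 2×2 table of presence of the other two types over
  the `n_C` triangles containing at least one `C` cell; the overall
  `ES_ABC` is the minimum of the three conditionals, so every
  conditional test must clear the threshold.  Degenerate margins
  (`n_C = 0` or a zero marginal) yield a flagged undefined result, never
  a silent 0.  Note that with very small type alphabets the three slots
  of a triangle make type presences structurally anti-correlated, so the
  null distribution of `ES` is inflated; null calibration should use a
  realistic panel width (≥ ~10 types).
* Two-sample two-sided proportion z-test with pooled variance;
  degenerate pooled proportions return p = 1 with a warning.
* Feature matrices: per sample, motif occurrences are dense-ranked and
  min–max scaled to [0, 1] (most abundant → 1; all-equal counts
  degenerate to 0 with a warning).
* Enrichment flags: a motif is enriched in a patient when it is among
  the patient's top-29 motifs of its own size; boundary ties are all
  included and never-observed motifs are never flagged.

## Robustness protocol

Perturbations act on the cell table, which is then re-triangulated from
scratch before re-counting:

* *missing* — exactly `round(rate·n)` uniformly chosen cells removed;
* *shift* — `round(rate·n)` cells displaced by `magnitude ×` the mean
  nearest-neighbor distance in a uniform random direction (per-cell
  scaling behind a flag); the protocol pairs rate and magnitude;
* *misclassify* — the types of `round(rate·n)` chosen cells are permuted
  among themselves, conserving the global type multiset (resampling from
  the empirical type frequencies behind a flag);
* *crop* — an axis-aligned window of side `fraction ×` the bounding box,
  placed uniformly.

Stability is the Spearman correlation between motif-abundance rankings
before and after, averaged over replicates: noise kinds run on rates
{0.01, 0.05, 0.1, 0.2, 0.5} with 100 replicates, cropping on fractions
0.1–0.9 with 10 replicates (a 0.01-fraction window of a 500-cell field
would hold fewer than 3 cells, so cropping keeps its own grid).

## Numerical and design notes

* Canonical motif forms come from BLISS canonical permutations with
  cell-type colors (igraph); a brute-force minimum-over-permutations
  serialization is the test oracle.  Equality and hashing of `Motif` go
  through the canonical string.
* Exact matching is VF2 (networkx `GraphMatcher`, induced semantics),
  counted per vertex subset so automorphic re-mappings collapse;
  an independent label-constrained subset enumeration provides a second
  exact path used for verification.
* Delaunay edges come from scipy's qhull; co-circular degeneracies
  resolve by the backend's tie-breaking and exact edge sets in such
  cases are implementation-defined.  Duplicate coordinates are rejected
  (jitter would silently change motif counts).  No long-edge pruning by
  default; a `max_edge_length` cutoff is available.
* Desk-scale problem sizes used by the test suite and the acceptance
  script (the package's own choices): ≥100 (graph, motif) oracle-
  equivalence pairs on graphs ≤64 nodes; a 2,000-pair corpus on ≤16-node
  graphs fully re-verified by enumeration; the ~4,800-pair training
  fixture above; planted-motif recovery on 6+6 case/control graphs of
  120 cells with 10 disjoint plantings per case sample; rank stability
  on 500-cell samples with 100 replicates per rate.

## Known limitations

* The synthetic generator's i.i.d. labels understate the spatial label
  correlation of real tissue; learned-classifier accuracies measured on
  it do not transfer to structured tissue without retraining.
* The classifier's accuracy degrades for motif sizes far outside its
  training range; exact counting remains available at any size, at VF2
  cost.
* Growth is greedy with a single seed per size (a beam flag exists);
  it can miss motifs whose sub-motifs are not themselves top-ranked.
* 2D coordinates only; no 3D triangulation.
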