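# ccmotif

Overrepresented **cellular-community motifs** in spatial omics.

Spatially resolved transcriptomics and proteomics (STARmap PLUS, CODEX,
MIBI-TOF, Xenium, ...) give each cell a position and a cell-type label.
`ccmotif` models a tissue region bottom-up as a *cellular community*:
the Delaunay triangulation of the cells, nodes labeled by type.  The
recurring units of multicellular organization are *CC motifs* — small
connected labeled graphs occurring as **induced** subgraphs of the
community.  The package finds and quantifies them:

* **Graph construction** — cell tables → triangulated cell graphs,
  hop-neighborhood *enclosed graphs*, motif-enriched regions.
* **Exact matching** — VF2 induced-subgraph testing/counting and exact
  censuses of typed nodes, edges and triangles.
* **Learned occurrence** — the occurrence `F(G, m) = Σ_v f(g_{v,2}, m)`
  is decomposed into per-node presence classifications; `f` is either
  the exact matcher or a trained GIN classifier with shortest-distance
  positional encoding (`SubgraphPresenceClassifier`, a scikit-learn
  estimator), making inference linear in the number of cells.
* **Pattern growth** — greedy size-incremental search: enumerate sizes
  1–3 exhaustively, pick the top motif by abundance or by case/control
  differential (Fisher exact test), grow it one typed node at a time.
* **Statistics** — Fisher/χ² with Bonferroni or Benjamini–Hochberg
  adjustment, Cramér's V effect sizes (including the conditional
  triangle variant with the 0.21 moderate-effect threshold), proportion
  tests, scaled dense-rank feature matrices and per-patient enrichment
  flags ready for survival/classification tooling.
* **Robustness** — cell dropout, coordinate shift, type
  misclassification and random cropping simulations with a Spearman
  rank-stability protocol.
* **Synthetic benchmarks** — seeded generators for random triangulated
  graphs and balanced, oracle-labeled (motif, target) training corpora.

For whom: computational biologists analyzing spatial omics cohorts who
want interpretable, topology-aware building blocks instead of top-down
neighborhood clusters.

## Worked example

```python
import numpy as np
from ccmotif import (build_cc, census_small, rank_motifs, estimate_occurrence,
                     enumerate_size_k, grow_to_size, NodeOccurrenceCounter)
from ccmotif.synthetic import random_cell_table

cells = random_cell_table(300, 4, np.random.default_rng(0))
G = build_cc(cells)                      # Delaunay cellular community
print(G.number_of_nodes(), G.number_of_edges())

counts = census_small(G, size=3)         # exact typed-triangle census
for motif, count, rank in rank_motifs(counts)[:3]:
    print(rank, motif.canonical, count)

top3 = rank_motifs(counts)[0][0]
res = estimate_occurrence("oracle", G, top3, hop=2)
print("presence-sum occurrence:", res.F)

counter = NodeOccurrenceCounter("oracle")
grown = grow_to_size(4, enumerate_size_k(sorted({c for c in cells.cell_type}), 3),
                     G, counter)
print("top size-4 motif:", grown.final.canonical)
```

Output:

```
300 881
1 3|t00,t01,t02|0-1;0-2;1-2 62
2 3|t01,t02,t03|0-1;0-2;1-2 61
3 3|t00,t02,t03|0-1;0-2;1-2 50
presence-sum occurrence: 244
top size-4 motif: 4|t01,t02,t03,t03|0-1;0-2;0-3;1-3;2-3
```

The census says the `t00–t01–t02` triangle is the most abundant typed
triangle (62 occurrences out of the graph's 586 triangles).  Its presence-sum
occurrence of 244 means 244 of the 300 cells have that triangle within
their 2-hop neighborhood.  Growing the seed yields the most abundant
size-4 motif, a diamond of one `t01`, one `t02` and two `t03` cells.

A command-line interface mirrors the workflow
(`ccmotif build-cc / census / count / grow / diff / features /
robustness / simulate-corpus / train`); every output table carries a
`.meta.json` sidecar with the seed and a configuration hash.

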