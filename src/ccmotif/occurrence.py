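"""Motif occurrence quantification on cellular-community graphs.

Two counting conventions are exposed and never conflated:

* the node-centric presence sum ``F(G, m) = sum_v f(g_{v,hop}, m)`` — the
  number of cells whose hop-neighborhood contains the motif; ``f`` is
  either the exact matcher or a trained presence classifier;
* the embedding census — the number of distinct vertex subsets inducing
  the motif (exact, enumeration-based for sizes 1-3).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .graph import enclosed_graph
from .match import contains_motif
from .motif import Motif

__all__ = ["OccurrenceResult", "estimate_occurrence", "census_small",
           "rank_motifs", "triangle_iter"]


@dataclass
class OccurrenceResult:
    motif: Motif
    graph_id: str
    F: int
    per_node_presence: dict
    mode: str  # "learned" | "oracle" | "census"

    def __post_init__(self):
        assert self.F == sum(self.per_node_presence.values())


def estimate_occurrence(classifier, G: nx.Graph, m: Motif, hop: int = 2,
                        graph_id: str = "") -> OccurrenceResult:
    """Presence-sum occurrence of ``m`` in ``G``.

    ``classifier`` is either the string ``"oracle"`` (exact matching on
    every enclosed graph) or a fitted presence classifier exposing
    ``predict_presence(graph, motif)``.
    """
    per_node: dict = {}
    if isinstance(classifier, str):
        if classifier != "oracle":
            raise ValueError(f"unknown classifier spec {classifier!r}")
        for v in G.nodes():
            sub = enclosed_graph(G, v, hop)
            per_node[v] = int(contains_motif(sub, m))
        mode = "oracle"
    else:
        for v in G.nodes():
            sub = enclosed_graph(G, v, hop)
            _, label = classifier.predict_presence(sub, m)
            per_node[v] = int(label)
        mode = "learned"
    return OccurrenceResult(motif=m, graph_id=graph_id,
                            F=sum(per_node.values()),
                            per_node_presence=per_node, mode=mode)


def triangle_iter(G: nx.Graph):
    """Yield each triangle of G exactly once as a node triple."""
    order = {n: i for i, n in enumerate(sorted(G.nodes(), key=str))}
    adj = {n: {u for u in G.neighbors(n)} for n in G.nodes()}
    for u, v in G.edges():
        if order[u] > order[v]:
            u, v = v, u
        for w in adj[u] & adj[v]:
            if order[w] > order[v]:
                yield (u, v, w)


def census_small(G: nx.Graph, size: int) -> dict[Motif, int]:
    """Exact labeled census of size-1 (nodes), size-2 (edges) or size-3
    (triangles) motifs, keyed by canonical motif."""
    if size not in (1, 2, 3):
        raise ValueError("census_small handles sizes 1-3 only")
    counts: Counter[Motif] = Counter()
    if size == 1:
        for _, d in G.nodes(data=True):
            counts[Motif([d["cell_type"]], [])] += 1
    elif size == 2:
        for u, v in G.edges():
            labs = sorted((G.nodes[u]["cell_type"], G.nodes[v]["cell_type"]))
            counts[Motif(labs, [(0, 1)])] += 1
    else:
        tri_edges = [(0, 1), (1, 2), (0, 2)]
        for u, v, w in triangle_iter(G):
            labs = sorted(G.nodes[x]["cell_type"] for x in (u, v, w))
            counts[Motif(labs, tri_edges)] += 1
    return dict(counts)


def rank_motifs(results: Iterable[OccurrenceResult] | Mapping[Motif, int]
                ) -> list[tuple[Motif, int, int]]:
    """Order motifs by descending occurrence with dense ranks (ties share a
    rank, no gaps); deterministic tie-break by canonical string."""
    if isinstance(results, Mapping):
        items = [(m, int(c)) for m, c in results.items()]
    else:
        items = [(r.motif, int(r.F)) for r in results]
    if not items:
        return []
    items.sort(key=lambda t: (-t[1], t[0].canonical))
    out = []
    rank = 0
    prev = None
    for m, f in items:
        if f != prev:
            rank += 1
            prev = f
        out.append((m, f, rank))
    return out
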