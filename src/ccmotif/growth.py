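"""Greedy size-incremental motif search.

Small motifs (sizes 1-3: typed nodes, typed edges, typed triangles) are
enumerated exhaustively; the top motif — by plain abundance or, with a
case/control design, by differential score — seeds a growth loop that
attaches one typed node per step.  The default attachment closes a
triangle on an existing edge of the seed, which keeps every candidate
realizable inside a planar triangulation; pendant (single-edge)
attachment is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Callable, Iterable, Sequence

import networkx as nx

from .graph import enclosed_graph
from .match import contains_motif
from .motif import Motif
from .stats import chi2_table, cramers_v, fisher_differential

__all__ = [
    "enumerate_size_k", "grow", "NodeOccurrenceCounter",
    "select_top", "select_top_differential", "grow_to_size",
    "DifferentialScore", "GrowthResult",
]


def enumerate_size_k(alphabet: Sequence[str], k: int) -> list[Motif]:
    """All size-k motifs on the given cell-type alphabet for k in 1..3.

    Size-3 uses the triangle topology only (motifs live in triangulations);
    larger sizes are reached by growth, not enumeration.
    """
    alphabet = sorted(set(alphabet))
    if k == 1:
        return [Motif([a], []) for a in alphabet]
    if k == 2:
        return [Motif(list(pair), [(0, 1)])
                for pair in combinations_with_replacement(alphabet, 2)]
    if k == 3:
        tri = [(0, 1), (1, 2), (0, 2)]
        return [Motif(list(trip), tri)
                for trip in combinations_with_replacement(alphabet, 3)]
    raise ValueError(f"size-{k} motifs are reached by growth, not enumeration")


def grow(seed: Motif, alphabet: Sequence[str],
         attachment: str = "triangle") -> list[Motif]:
    """Candidate motifs of size k+1 from a size-k seed.

    ``triangle`` attachment adds one node of each type connected to both
    endpoints of each existing edge; a seed without edges (k = 1) falls
    back to a single-edge attachment, as does ``attachment="pendant"``.
    Candidates are canonical-deduplicated.
    """
    if attachment not in ("triangle", "pendant"):
        raise ValueError(f"unknown attachment rule {attachment!r}")
    alphabet = sorted(set(alphabet))
    out: dict[str, Motif] = {}
    new = seed.k
    if attachment == "pendant" or not seed.edges:
        for anchor in range(seed.k):
            for t in alphabet:
                cand = Motif(list(seed.labels) + [t],
                             list(seed.edges) + [(anchor, new)])
                out.setdefault(cand.canonical, cand)
    else:
        for u, w in seed.edges:
            for t in alphabet:
                cand = Motif(list(seed.labels) + [t],
                             list(seed.edges) + [(u, new), (w, new)])
                out.setdefault(cand.canonical, cand)
    return list(out.values())


class NodeOccurrenceCounter:
    """Node-centric occurrence counter F(G, m) with cached enclosed graphs.

    ``classifier`` is ``"oracle"`` for exact matching or a fitted presence
    classifier.  The per-graph enclosed-graph decomposition is cached, so
    scoring many candidate motifs against the same graphs stays cheap.
    ``sites(G)`` returns the number of eligible sites (nodes), the
    denominator used in differential 2x2 tables.
    """

    def __init__(self, classifier="oracle", hop: int = 2):
        self.classifier = classifier
        self.hop = hop
        self._cache: dict[int, list] = {}
        self._summaries: dict[int, list] = {}

    def _enclosed(self, G: nx.Graph) -> list:
        key = id(G)
        if key not in self._cache:
            self._cache[key] = [enclosed_graph(G, v, self.hop)
                                for v in G.nodes()]
        return self._cache[key]

    def _summarize(self, G: nx.Graph) -> list:
        """Per enclosed graph: the sets of node labels, edge label pairs and
        triangle label multisets — exact presence answers for census-shaped
        motifs without a subgraph-isomorphism search."""
        key = id(G)
        if key not in self._summaries:
            from .occurrence import triangle_iter
            out = []
            for sub in self._enclosed(G):
                lab = {d["cell_type"] for _, d in sub.nodes(data=True)}
                edges = {tuple(sorted((sub.nodes[u]["cell_type"],
                                       sub.nodes[v]["cell_type"])))
                         for u, v in sub.edges()}
                tris = {tuple(sorted(sub.nodes[x]["cell_type"]
                                     for x in t))
                        for t in triangle_iter(sub)}
                out.append((lab, edges, tris))
            self._summaries[key] = out
        return self._summaries[key]

    @staticmethod
    def _motif_triangles(m: Motif) -> set:
        tris = set()
        for u, v in m.edges:
            for w in range(m.k):
                if (min(u, w), max(u, w)) in m.edges and \
                        (min(v, w), max(v, w)) in m.edges:
                    tris.add(tuple(sorted((m.labels[u], m.labels[v],
                                           m.labels[w]))))
        return tris

    @staticmethod
    def _census_shape(m: Motif) -> int | None:
        """1/2/3 when the motif is a typed node / edge / triangle."""
        if m.k == 1:
            return 1
        if m.k == 2 and len(m.edges) == 1:
            return 2
        if m.k == 3 and len(m.edges) == 3:
            return 3
        return None

    def __call__(self, G: nx.Graph, m: Motif) -> int:
        if isinstance(self.classifier, str):
            if self.classifier != "oracle":
                raise ValueError(f"unknown classifier {self.classifier!r}")
            shape = self._census_shape(m)
            if shape is not None:
                key = m.label_multiset()
                summaries = self._summarize(G)
                if shape == 1:
                    return sum(key[0] in lab for lab, _, _ in summaries)
                if shape == 2:
                    return sum(key in edges for _, edges, _ in summaries)
                return sum(key in tris for _, _, tris in summaries)
            # an induced occurrence of m restricts to an induced occurrence
            # of each of m's triangles: cheap necessary condition first
            need = self._motif_triangles(m)
            summaries = self._summarize(G)
            subs = self._enclosed(G)
            total = 0
            for sub, (_, _, tris) in zip(subs, summaries):
                if need <= tris and contains_motif(sub, m):
                    total += 1
            return total
        return sum(self.classifier.predict_presence(s, m)[1]
                   for s in self._enclosed(G))

    @staticmethod
    def sites(G: nx.Graph) -> int:
        return G.number_of_nodes()


@dataclass
class DifferentialScore:
    motif: Motif
    f_case: int
    f_control: int
    total_case: int
    total_control: int
    p: float | None
    score: float
    direction: int
    metadata: dict = field(default_factory=dict)


@dataclass
class GrowthResult:
    seed: Motif
    trace: list[dict]
    final: Motif


def _as_graphs(G) -> list[nx.Graph]:
    return [G] if isinstance(G, nx.Graph) else list(G)


def select_top(candidates: Iterable[Motif], G, counter: Callable,
               return_scores: bool = False):
    """Motif with the maximum summed occurrence over the graph collection;
    ties broken by lexicographically smallest canonical string."""
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    graphs = _as_graphs(G)
    scores = {m: sum(counter(g, m) for g in graphs) for m in candidates}
    best = min(scores, key=lambda m: (-scores[m], m.canonical))
    if return_scores:
        return best, scores
    return best


def select_top_differential(candidates: Iterable[Motif], G_case, G_control,
                            counter: Callable, score: str = "fisher",
                            sites: Callable | None = None,
                            prefer_enriched: bool = True,
                            ) -> tuple[Motif, DifferentialScore, dict]:
    """Motif that best separates the two conditions.

    Per candidate, occurrences are summed over each condition's graphs and
    laid out on the 2x2 table [occurrences, eligible sites without the
    motif] x condition.  ``score="fisher"`` ranks by -log10 of the
    two-sided Fisher p; ``score="effect_size"`` by Cramér's V of the same
    table.  With ``prefer_enriched`` (the default) candidates enriched in
    the case condition outrank depleted ones regardless of score, keeping
    the search aimed at overrepresentation; the score itself stays
    two-sided.  Returns (winner, its score record, all score records).
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate set")
    cases, controls = _as_graphs(G_case), _as_graphs(G_control)
    if not cases or not controls:
        raise ValueError("both conditions need at least one graph")
    sites = sites or getattr(counter, "sites", None)
    if sites is None:
        raise ValueError("a sites() function is required for the 2x2 margins")
    total_case = sum(sites(g) for g in cases)
    total_control = sum(sites(g) for g in controls)
    if total_case == 0 or total_control == 0:
        raise ValueError("zero total sites in a condition")
    records: dict[Motif, DifferentialScore] = {}
    for m in candidates:
        f_case = sum(counter(g, m) for g in cases)
        f_control = sum(counter(g, m) for g in controls)
        direction, p = fisher_differential(f_case, total_case,
                                           f_control, total_control)
        if score == "fisher":
            val = -math.log10(max(p, 1e-300))
        elif score == "effect_size":
            table = [[f_case, total_case - f_case],
                     [f_control, total_control - f_control]]
            try:
                val = cramers_v(chi2_table(table), total_case + total_control)
            except ValueError:
                val = 0.0
        else:
            raise ValueError(f"unknown score {score!r}")
        records[m] = DifferentialScore(
            motif=m, f_case=f_case, f_control=f_control,
            total_case=total_case, total_control=total_control,
            p=p, score=val, direction=direction,
            metadata={"margins": "sites-without-motif", "score": score})
    if prefer_enriched:
        key = lambda m: (-records[m].direction, -records[m].score, m.canonical)
    else:
        key = lambda m: (-records[m].score, m.canonical)
    best = min(records, key=key)
    return best, records[best], records


def grow_to_size(K: int, start: Iterable[Motif], G, counter: Callable,
                 G_control=None, score: str = "fisher",
                 alphabet: Sequence[str] | None = None,
                 attachment: str = "triangle") -> GrowthResult:
    """Iterate select -> grow from a starting motif set up to size K.

    With ``G_control`` given, selection maximizes the differential score of
    case (``G``) vs control; otherwise plain summed abundance on ``G``.
    The per-size trace records every candidate set with its scores.
    """
    start = list(start)
    if not start:
        raise ValueError("empty starting motif set")
    sizes = {m.k for m in start}
    if len(sizes) != 1:
        raise ValueError("starting motifs must share one size")
    k0 = sizes.pop()
    if K < k0:
        raise ValueError(f"target size {K} below starting size {k0}")
    if alphabet is None:
        alphabet = sorted({lab for m in start for lab in m.labels})

    trace: list[dict] = []
    candidates = start
    current = None
    k = k0
    while True:
        if G_control is None:
            current, scores = select_top(candidates, G, counter,
                                         return_scores=True)
            step_scores = {m: float(s) for m, s in scores.items()}
        else:
            current, _, records = select_top_differential(
                candidates, G, G_control, counter, score=score)
            step_scores = {m: r.score for m, r in records.items()}
        trace.append({"size": k, "candidates": candidates,
                      "scores": step_scores, "selected": current})
        if k == K:
            break
        candidates = grow(current, alphabet, attachment=attachment)
        k += 1
    return GrowthResult(seed=trace[0]["selected"], trace=trace, final=current)
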