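"""Exact induced-subgraph isomorphism testing and counting.

Matching uses *induced* semantics throughout: a motif occurs on a vertex
subset only if the subgraph induced by that subset is label-isomorphic to
the motif, non-edges included.  Occurrences are counted per vertex subset,
not per mapping, so automorphic re-mappings of the same cells count once.

Two independent code paths are provided: a VF2 search (`contains_motif`,
`count_embeddings`) and a label-constrained subset enumeration
(`contains_motif_exhaustive`) used to cross-check the first.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict

import networkx as nx
from networkx.algorithms import isomorphism as iso

from .graph import enclosed_graph
from .motif import Motif

__all__ = [
    "contains_motif",
    "count_embeddings",
    "find_embeddings",
    "oracle_node_count",
    "contains_motif_exhaustive",
    "count_embeddings_exhaustive",
    "suggested_hop",
]

_NODE_MATCH = iso.categorical_node_match("cell_type", None)


def _label_counts(g: nx.Graph) -> Counter:
    return Counter(nx.get_node_attributes(g, "cell_type").values())


def _passes_label_filter(g: nx.Graph, m: Motif) -> bool:
    if g.number_of_nodes() < m.k:
        return False
    have = _label_counts(g)
    need = Counter(m.labels)
    return all(have.get(lab, 0) >= c for lab, c in need.items())


def contains_motif(g: nx.Graph, m: Motif) -> bool:
    """True iff some node subset of ``g`` induces a graph label-isomorphic
    to ``m``."""
    if not _passes_label_filter(g, m):
        return False
    gm = iso.GraphMatcher(g, m.to_networkx(), node_match=_NODE_MATCH)
    return gm.subgraph_is_isomorphic()


def find_embeddings(g: nx.Graph, m: Motif) -> list[frozenset]:
    """All distinct vertex subsets of ``g`` inducing ``m``."""
    if not _passes_label_filter(g, m):
        return []
    gm = iso.GraphMatcher(g, m.to_networkx(), node_match=_NODE_MATCH)
    seen: set[frozenset] = set()
    for mapping in gm.subgraph_isomorphisms_iter():
        seen.add(frozenset(mapping.keys()))
    return sorted(seen, key=lambda s: sorted(map(str, s)))


def count_embeddings(g: nx.Graph, m: Motif) -> int:
    """Number of distinct vertex subsets of ``g`` inducing ``m``."""
    return len(find_embeddings(g, m))


def oracle_node_count(G: nx.Graph, m: Motif, hop: int = 2) -> int:
    """Exact node-centric occurrence: the number of nodes whose
    ``hop``-neighborhood enclosed graph contains the motif.

    This is the exact value of the presence-sum occurrence F(G, m) that the
    learned classifier estimates.
    """
    total = 0
    for v in G.nodes():
        sub = enclosed_graph(G, v, hop)
        if contains_motif(sub, m):
            total += 1
    return total


def suggested_hop(m: Motif) -> int:
    """Neighborhood radius large enough for the motif to fit in an enclosed
    graph: half the motif diameter, rounded up (never applied silently)."""
    d = m.diameter()
    return max(1, -(-d // 2))


# -- independent enumeration oracle ---------------------------------------


def _grouped_assignments(g: nx.Graph, m: Motif):
    """Yield mappings motif-index -> g-node with matching labels, grouped so
    that only label-compatible subsets are enumerated."""
    nodes_by_label: dict[str, list] = defaultdict(list)
    for n, data in g.nodes(data=True):
        nodes_by_label[data["cell_type"]].append(n)
    motif_by_label: dict[str, list[int]] = defaultdict(list)
    for i, lab in enumerate(m.labels):
        motif_by_label[lab].append(i)
    labels = sorted(motif_by_label)
    for lab in labels:
        if len(nodes_by_label.get(lab, ())) < len(motif_by_label[lab]):
            return
    pools = [
        itertools.combinations(nodes_by_label[lab], len(motif_by_label[lab]))
        for lab in labels
    ]
    for chosen in itertools.product(*pools):
        perm_pools = [itertools.permutations(group) for group in chosen]
        for perms in itertools.product(*perm_pools):
            mapping: dict[int, object] = {}
            for lab, assigned in zip(labels, perms):
                for mi, gn in zip(motif_by_label[lab], assigned):
                    mapping[mi] = gn
            yield mapping


def _mapping_is_induced(g: nx.Graph, m: Motif, mapping: dict[int, object]) -> bool:
    for i in range(m.k):
        for j in range(i + 1, m.k):
            if g.has_edge(mapping[i], mapping[j]) != ((i, j) in m.edges):
                return False
    return True


def contains_motif_exhaustive(g: nx.Graph, m: Motif) -> bool:
    """Subset-enumeration reference for :func:`contains_motif` (small graphs
    only); shares no search code with the VF2 path."""
    for mapping in _grouped_assignments(g, m):
        if _mapping_is_induced(g, m, mapping):
            return True
    return False


def count_embeddings_exhaustive(g: nx.Graph, m: Motif) -> int:
    """Subset-enumeration reference for :func:`count_embeddings`."""
    hits: set[frozenset] = set()
    for mapping in _grouped_assignments(g, m):
        if _mapping_is_induced(g, m, mapping):
            hits.add(frozenset(mapping.values()))
    return len(hits)


def relabel_types(g: nx.Graph, mapping: dict[str, str]) -> nx.Graph:
    """Consistently rename cell types on a copy of ``g`` (used for the
    label-permutation equivariance property)."""
    out = g.copy()
    for _, data in out.nodes(data=True):
        data["cell_type"] = mapping.get(data["cell_type"], data["cell_type"])
    return out
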