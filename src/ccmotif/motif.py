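"""Small labeled query graphs (cellular-community motifs).

A motif is a connected, undirected graph on a handful of nodes, each node
carrying a cell-type label.  Motifs are value objects: equality and hashing
go through a label-aware canonical form so that any two label-isomorphic
motifs compare equal regardless of node ordering.
"""

from __future__ import annotations

import itertools
import json
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx

__all__ = [
    "Motif",
    "read_motif",
    "write_motif",
    "brute_force_canonical",
]


class Motif:
    """A connected labeled graph used as a subgraph-matching query.

    Parameters
    ----------
    labels:
        Cell-type label per node; node ids are the positions ``0..k-1``.
    edges:
        Undirected edges as pairs of node indices.
    """

    __slots__ = ("labels", "edges", "_canonical")

    def __init__(self, labels: Sequence[str], edges: Iterable[tuple[int, int]]):
        labels = tuple(str(l) for l in labels)
        k = len(labels)
        if k < 1:
            raise ValueError("a motif needs at least one node")
        norm = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if u == v:
                raise ValueError(f"self-loop on node {u}")
            if not (0 <= u < k and 0 <= v < k):
                raise ValueError(f"edge ({u},{v}) references a missing node")
            norm.add((min(u, v), max(u, v)))
        self.labels = labels
        self.edges = frozenset(norm)
        if not self._connected():
            raise ValueError("motif must be connected")
        self._canonical: str | None = None

    # -- basic protocol ----------------------------------------------------

    @property
    def k(self) -> int:
        """Number of nodes (the motif size)."""
        return len(self.labels)

    def _connected(self) -> bool:
        if self.k == 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(self.k)}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        seen = {0}
        stack = [0]
        while stack:
            for w in adj[stack.pop()]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.k

    @property
    def canonical(self) -> str:
        """Canonical string; identical for all label-isomorphic motifs."""
        if self._canonical is None:
            self._canonical = _canonical_form(self.labels, self.edges)
        return self._canonical

    def __eq__(self, other) -> bool:
        return isinstance(other, Motif) and self.canonical == other.canonical

    def __hash__(self) -> int:
        return hash(self.canonical)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Motif({self.canonical})"

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, lab in enumerate(self.labels):
            g.add_node(i, cell_type=lab)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, label_attr: str = "cell_type") -> "Motif":
        nodes = list(g.nodes())
        index = {n: i for i, n in enumerate(nodes)}
        labels = [g.nodes[n][label_attr] for n in nodes]
        edges = [(index[u], index[v]) for u, v in g.edges()]
        return cls(labels, edges)

    def relabel(self, mapping: Mapping[str, str] | Sequence[str]) -> "Motif":
        """Return a copy with labels substituted.

        ``mapping`` is either a dict old-label -> new-label or a sequence of
        k new labels in node order.
        """
        if isinstance(mapping, Mapping):
            labels = [mapping.get(l, l) for l in self.labels]
        else:
            if len(mapping) != self.k:
                raise ValueError("label sequence length must equal motif size")
            labels = list(mapping)
        return Motif(labels, self.edges)

    def diameter(self) -> int:
        return nx.diameter(self.to_networkx()) if self.k > 1 else 0

    def label_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(self.labels))


def _canonical_form(labels: Sequence[str], edges: Iterable[tuple[int, int]]) -> str:
    k = len(labels)
    palette = {lab: i for i, lab in enumerate(sorted(set(labels)))}
    g = ig.Graph(k, list(edges))
    perm = g.canonical_permutation(color=[palette[l] for l in labels])
    new_labels = [None] * k
    for old, new in enumerate(perm):
        new_labels[new] = labels[old]
    new_edges = sorted(
        (min(perm[u], perm[v]), max(perm[u], perm[v])) for u, v in edges
    )
    lab_part = ",".join(new_labels)  # type: ignore[arg-type]
    edge_part = ";".join(f"{u}-{v}" for u, v in new_edges)
    return f"{k}|{lab_part}|{edge_part}"


def brute_force_canonical(labels: Sequence[str], edges: Iterable[tuple[int, int]]) -> str:
    """Reference canonicalization: minimum serialization over all node
    permutations.  Exponential; only sensible for k <= 7."""
    k = len(labels)
    edges = [(min(u, v), max(u, v)) for u, v in edges]
    best = None
    for perm in itertools.permutations(range(k)):
        lab = [None] * k
        for old, new in enumerate(perm):
            lab[new] = labels[old]
        es = sorted((min(perm[u], perm[v]), max(perm[u], perm[v])) for u, v in edges)
        key = (tuple(lab), tuple(es))
        if best is None or key < best:
            best = key
    lab_part = ",".join(best[0])
    edge_part = ";".join(f"{u}-{v}" for u, v in best[1])
    return f"{k}|{lab_part}|{edge_part}"


# -- structured-text serialization ----------------------------------------


def motif_to_dict(m: Motif) -> dict:
    return {
        "nodes": [{"id": i, "label": lab} for i, lab in enumerate(m.labels)],
        "edges": [[u, v] for u, v in sorted(m.edges)],
    }


def motif_from_dict(d: Mapping) -> Motif:
    try:
        nodes = d["nodes"]
        raw_edges = d["edges"]
    except KeyError as e:  # pragma: no cover - message path
        raise ValueError(f"motif document lacks required field {e}") from e
    ids = [n["id"] for n in nodes]
    index = {nid: i for i, nid in enumerate(ids)}
    if len(index) != len(ids):
        raise ValueError("duplicate node ids in motif document")
    labels = [str(n["label"]) for n in nodes]
    edges = [(index[u], index[v]) for u, v in raw_edges]
    return Motif(labels, edges)


def write_motif(m: Motif, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(motif_to_dict(m), fh, indent=1)
        fh.write("\n")


def read_motif(path) -> Motif:
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"{path}: empty motif file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: malformed motif file at line {e.lineno}: {e.msg}") from e
    return motif_from_dict(doc)
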