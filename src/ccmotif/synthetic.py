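"""Synthetic benchmark generation.

Emulates the benchmark regime used to train and evaluate the presence
classifier: target graphs are Delaunay triangulations of uniform random
planar points with i.i.d. uniform cell-type labels; query motifs are small
connected topologies sampled from real triangulations and decorated with
label permutations; every (motif, target) pair carries an exact
presence/absence label from the VF2 oracle, balanced 1:1 and split 8:1:1.

The generator deliberately does not model cell-type spatial autocorrelation
or tissue architecture — labels are i.i.d., as in the benchmark it mirrors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import isomorphism as iso

from .graph import build_cc
from .match import contains_motif
from .motif import Motif

__all__ = [
    "CorpusSpec",
    "TrainingPair",
    "Corpus",
    "GenerationError",
    "default_alphabet",
    "random_cell_table",
    "random_triangulated_graph",
    "motif_library",
    "generate_training_corpus",
    "generate_independent_test_set",
    "plant_motif",
    "make_case_control",
    "save_corpus",
    "load_corpus",
]


class GenerationError(RuntimeError):
    """Raised when a requested corpus cannot be generated (e.g. balance or
    disjointness is unachievable within the retry budget)."""


def default_alphabet(n_types: int) -> list[str]:
    return [f"t{i:02d}" for i in range(n_types)]


def _default_graph_sizes() -> dict[int, tuple[int, ...]]:
    sizes: dict[int, tuple[int, ...]] = {}
    for k in range(3, 7):
        sizes[k] = (16, 32)
    for k in range(7, 10):
        sizes[k] = (32, 64)
    return sizes


@dataclass
class CorpusSpec:
    """Generation recipe for a labeled benchmark corpus.

    Defaults mirror the benchmark regime: motif sizes 3-9 in several
    topologies, 8/16/32 node types, 16/32-node targets for sizes 3-6 and
    32/64-node targets for sizes 7-9, 50 label permutations per topology,
    1000 target graphs per permutation, positives:negatives 1:1, split
    8:1:1.  Desk-scale corpora shrink the counts, not the structure.
    """

    motif_sizes: tuple[int, ...] = (3, 4, 5, 6, 7, 8, 9)
    topologies_per_size: int = 1
    node_type_counts: tuple[int, ...] = (8, 16, 32)
    graph_sizes: dict[int, tuple[int, ...]] = field(default_factory=_default_graph_sizes)
    permutations_per_motif: int = 50
    graphs_per_permutation: int = 1000
    positive_fraction: float = 0.5
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    retry_budget: int = 200
    seed: int = 0

    def __post_init__(self):
        if not all(3 <= k <= 9 for k in self.motif_sizes):
            raise ValueError("motif sizes must lie in 3..9")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ValueError("positive_fraction must be in (0,1)")


class TrainingPair(NamedTuple):
    motif: Motif
    target: nx.Graph
    label: int


@dataclass
class Corpus:
    spec: CorpusSpec
    train: list[TrainingPair]
    val: list[TrainingPair]
    test: list[TrainingPair]
    registry: set[str]  # canonical strings of every labeled motif used

    @property
    def pairs(self) -> list[TrainingPair]:
        return self.train + self.val + self.test


# -- random graphs ---------------------------------------------------------


def random_cell_table(n: int, n_types: int, rng: np.random.Generator,
                      alphabet: Sequence[str] | None = None) -> pd.DataFrame:
    if alphabet is None:
        alphabet = default_alphabet(n_types)
    pts = rng.random((n, 2))
    labels = rng.integers(0, len(alphabet), size=n)
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": pts[:, 0],
        "y": pts[:, 1],
        "cell_type": [alphabet[i] for i in labels],
    })


def random_triangulated_graph(n: int, n_types: int, seed: int | np.random.Generator,
                              alphabet: Sequence[str] | None = None) -> nx.Graph:
    """Delaunay graph of ``n`` uniform random points with i.i.d. uniform
    type labels; deterministic for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return build_cc(random_cell_table(n, n_types, rng, alphabet))


# -- motif topology library ------------------------------------------------


def _topology_canonical(g: nx.Graph) -> str:
    m = Motif(["x"] * g.number_of_nodes(),
              [(list(g.nodes()).index(u), list(g.nodes()).index(v)) for u, v in g.edges()])
    return m.canonical


def _sample_connected_subgraph(G: nx.Graph, k: int, rng: np.random.Generator) -> list:
    nodes = list(G.nodes())
    start = nodes[rng.integers(len(nodes))]
    chosen = [start]
    frontier = set(G.neighbors(start))
    while len(chosen) < k:
        if not frontier:
            return []
        pick = sorted(frontier)[rng.integers(len(frontier))]
        chosen.append(pick)
        frontier |= set(G.neighbors(pick))
        frontier -= set(chosen)
    return chosen


def _as_topology(G: nx.Graph, nodes: Sequence) -> Motif:
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in G.subgraph(nodes).edges()]
    return Motif(["x"] * len(nodes), edges)


def motif_library(sizes: Iterable[int], topologies_per_size: int, seed: int,
                  probe_nodes: int = 48, max_attempts: int = 4000) -> dict[int, list[Motif]]:
    """Sample connected, pairwise non-isomorphic unlabeled topologies per
    size, each realizable in a planar triangulation by construction (they
    are cut directly out of random Delaunay graphs).  The size-3 set always
    contains the triangle."""
    rng = np.random.default_rng(seed)
    out: dict[int, list[Motif]] = {}
    for k in sorted(set(sizes)):
        if not 3 <= k <= 9:
            raise GenerationError(f"motif size {k} outside supported range 3..9")
        found: dict[str, Motif] = {}
        if k == 3:
            tri = Motif(["x", "x", "x"], [(0, 1), (1, 2), (0, 2)])
            found[tri.canonical] = tri
        attempts = 0
        probe = random_triangulated_graph(probe_nodes, 1, rng)
        while len(found) < topologies_per_size and attempts < max_attempts:
            attempts += 1
            if attempts % 200 == 0:  # fresh probe graph for more diversity
                probe = random_triangulated_graph(probe_nodes, 1, rng)
            nodes = _sample_connected_subgraph(probe, k, rng)
            if not nodes:
                continue
            topo = _as_topology(probe, nodes)
            found.setdefault(topo.canonical, topo)
        if len(found) < topologies_per_size:
            raise GenerationError(
                f"could only realize {len(found)}/{topologies_per_size} "
                f"size-{k} topologies in random triangulations")
        out[k] = list(found.values())[:topologies_per_size]
    return out


# -- planting and pair generation -----------------------------------------


def _structural_embeddings(G: nx.Graph, topo: Motif, cap: int = 400) -> list[dict]:
    """Up to ``cap`` induced embeddings of an unlabeled topology in G, as
    mappings motif-index -> graph node."""
    gm = iso.GraphMatcher(G, topo.to_networkx())
    out = []
    seen: set[frozenset] = set()
    for mapping in gm.subgraph_isomorphisms_iter():
        key = frozenset(mapping.keys())
        if key in seen:
            continue
        seen.add(key)
        out.append({mi: gn for gn, mi in mapping.items()})
        if len(out) >= cap:
            break
    return out


def plant_motif(G: nx.Graph, m: Motif, rng: np.random.Generator,
                n_plant: int = 1, disjoint: bool = True) -> int:
    """Relabel nodes of ``G`` in place so that ``m`` occurs on up to
    ``n_plant`` (optionally node-disjoint) locations; returns the number of
    plantings made.  Planting only rewrites cell types on an existing
    embedding of the motif's topology, so the graph stays a valid
    triangulation."""
    topo = Motif(["x"] * m.k, m.edges)
    embeddings = _structural_embeddings(G, topo)
    if not embeddings:
        return 0
    order = rng.permutation(len(embeddings))
    used: set = set()
    planted = 0
    for idx in order:
        mapping = embeddings[idx]
        nodes = set(mapping.values())
        if disjoint and nodes & used:
            continue
        for mi, gn in mapping.items():
            G.nodes[gn]["cell_type"] = m.labels[mi]
        used |= nodes
        planted += 1
        if planted >= n_plant:
            break
    return planted


def _positive_pair(m: Motif, n_nodes: int, n_types: int, alphabet,
                   rng, budget: int) -> nx.Graph:
    for _ in range(budget):
        G = random_triangulated_graph(n_nodes, n_types, rng, alphabet)
        if plant_motif(G, m, rng, n_plant=1):
            if contains_motif(G, m):
                return G
    raise GenerationError(
        f"could not realize a positive target for motif {m.canonical} "
        f"within {budget} attempts")


def _negative_pair(m: Motif, n_nodes: int, n_types: int, alphabet,
                   rng, budget: int) -> nx.Graph:
    for _ in range(budget):
        G = random_triangulated_graph(n_nodes, n_types, rng, alphabet)
        if not contains_motif(G, m):
            return G
    raise GenerationError(
        f"could not sample a negative target for motif {m.canonical} "
        f"within {budget} attempts (motif near-ubiquitous)")


def _sample_label_permutations(topo: Motif, alphabet: Sequence[str], count: int,
                               rng: np.random.Generator,
                               exclude: set[str] | None = None,
                               budget_factor: int = 50) -> list[Motif]:
    """Sample ``count`` distinct labeled variants of a topology, without
    replacement with respect to label-isomorphism, optionally avoiding the
    canonical forms in ``exclude``."""
    exclude = exclude or set()
    total = len(alphabet) ** topo.k
    if total < count:
        raise GenerationError(
            f"alphabet of {len(alphabet)} types admits only {total} "
            f"assignments for a size-{topo.k} motif; {count} requested")
    out: list[Motif] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = budget_factor * count
    while len(out) < count and attempts < max_attempts:
        attempts += 1
        labels = [alphabet[i] for i in rng.integers(0, len(alphabet), size=topo.k)]
        cand = Motif(labels, topo.edges)
        if cand.canonical in seen or cand.canonical in exclude:
            continue
        seen.add(cand.canonical)
        out.append(cand)
    if len(out) < count:
        raise GenerationError(
            f"could not find {count} fresh label permutations "
            f"(alphabet too small or registry too dense)")
    return out


def _generate_pairs(spec: CorpusSpec, rng: np.random.Generator,
                    exclude: set[str] | None = None,
                    graphs_per_permutation: int | None = None,
                    ) -> tuple[list[TrainingPair], set[str]]:
    library = motif_library(spec.motif_sizes, spec.topologies_per_size,
                            int(rng.integers(2**31)))
    gpp = graphs_per_permutation or spec.graphs_per_permutation
    pairs: list[TrainingPair] = []
    registry: set[str] = set()
    for k in spec.motif_sizes:
        for topo in library[k]:
            for n_types in spec.node_type_counts:
                alphabet = default_alphabet(n_types)
                motifs = _sample_label_permutations(
                    topo, alphabet, spec.permutations_per_motif, rng, exclude)
                for m in motifs:
                    registry.add(m.canonical)
                    n_pos = int(round(gpp * spec.positive_fraction))
                    n_neg = gpp - n_pos
                    for i in range(gpp):
                        n_nodes = int(rng.choice(spec.graph_sizes[k]))
                        if i < n_pos:
                            G = _positive_pair(m, n_nodes, n_types, alphabet,
                                               rng, spec.retry_budget)
                            label = 1
                        else:
                            G = _negative_pair(m, n_nodes, n_types, alphabet,
                                               rng, spec.retry_budget)
                            label = 0
                        assert contains_motif(G, m) == label
                        pairs.append(TrainingPair(m, G, label))
    return pairs, registry


def _stratified_split(pairs: list[TrainingPair], split: tuple[float, float, float],
                      rng: np.random.Generator):
    by_stratum: dict[tuple[int, int], list[TrainingPair]] = {}
    for p in pairs:
        by_stratum.setdefault((p.motif.k, p.label), []).append(p)
    buckets: tuple[list, list, list] = ([], [], [])
    for stratum in sorted(by_stratum):
        group = by_stratum[stratum]
        order = rng.permutation(len(group))
        n = len(group)
        n_train = int(round(split[0] * n))
        n_val = int(round(split[1] * n))
        for j, idx in enumerate(order):
            if j < n_train:
                buckets[0].append(group[idx])
            elif j < n_train + n_val:
                buckets[1].append(group[idx])
            else:
                buckets[2].append(group[idx])
    return buckets


def generate_training_corpus(spec: CorpusSpec) -> Corpus:
    """Generate a balanced, oracle-labeled corpus split 8:1:1 (stratified by
    motif size and label)."""
    rng = np.random.default_rng(spec.seed)
    pairs, registry = _generate_pairs(spec, rng)
    train, val, test = _stratified_split(pairs, spec.split, rng)
    return Corpus(spec=spec, train=train, val=val, test=test, registry=registry)


def generate_independent_test_set(spec: CorpusSpec, exclude: set[str],
                                  graphs_per_permutation: int | None = None,
                                  ) -> list[TrainingPair]:
    """Fresh label permutations disjoint from a training registry, with the
    same balanced pair construction."""
    rng = np.random.default_rng(spec.seed + 1)
    pairs, registry = _generate_pairs(
        spec, rng, exclude=exclude,
        graphs_per_permutation=graphs_per_permutation)
    overlap = registry & exclude
    if overlap:  # defensive; _sample_label_permutations already excludes
        raise GenerationError(f"registry overlap: {sorted(overlap)[:3]}")
    return pairs


# -- planted case/control collections -------------------------------------


def make_case_control(planted: Motif, n_case: int, n_control: int, n_nodes: int,
                      n_types: int, plants_per_case: int, seed: int,
                      ) -> tuple[list[nx.Graph], list[nx.Graph]]:
    """Simulated differential design: control graphs are plain random
    triangulations; case graphs additionally carry ``plants_per_case``
    node-disjoint planted occurrences of the motif."""
    rng = np.random.default_rng(seed)
    alphabet = default_alphabet(n_types)
    cases, controls = [], []
    for _ in range(n_case):
        G = random_triangulated_graph(n_nodes, n_types, rng, alphabet)
        plant_motif(G, planted, rng, n_plant=plants_per_case)
        cases.append(G)
    for _ in range(n_control):
        controls.append(random_triangulated_graph(n_nodes, n_types, rng, alphabet))
    return cases, controls


# -- serialization ---------------------------------------------------------


def _graph_to_jsonable(G: nx.Graph) -> dict:
    return {
        "nodes": [
            {"id": str(n), "label": d["cell_type"],
             "x": d.get("x"), "y": d.get("y")}
            for n, d in G.nodes(data=True)
        ],
        "edges": [[str(u), str(v)] for u, v in G.edges()],
    }


def _graph_from_jsonable(doc: dict) -> nx.Graph:
    g = nx.Graph()
    for nd in doc["nodes"]:
        attrs = {"cell_type": nd["label"]}
        if nd.get("x") is not None:
            attrs["x"] = float(nd["x"])
            attrs["y"] = float(nd["y"])
        g.add_node(nd["id"], **attrs)
    g.add_edges_from((u, v) for u, v in doc["edges"])
    return g


def save_corpus(corpus: Corpus, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = asdict(corpus.spec)
    spec["graph_sizes"] = {str(k): list(v) for k, v in spec["graph_sizes"].items()}
    manifest = {"spec": spec, "registry": sorted(corpus.registry)}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    from .motif import motif_to_dict
    for name in ("train", "val", "test"):
        with open(directory / f"{name}.jsonl", "w", encoding="utf-8") as fh:
            for pair in getattr(corpus, name):
                fh.write(json.dumps({
                    "motif": motif_to_dict(pair.motif),
                    "graph": _graph_to_jsonable(pair.target),
                    "label": pair.label,
                }) + "\n")


def load_corpus(directory) -> Corpus:
    from .motif import motif_from_dict
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    spec_doc = manifest["spec"]
    spec_doc["motif_sizes"] = tuple(spec_doc["motif_sizes"])
    spec_doc["node_type_counts"] = tuple(spec_doc["node_type_counts"])
    spec_doc["split"] = tuple(spec_doc["split"])
    spec_doc["graph_sizes"] = {int(k): tuple(v)
                               for k, v in spec_doc["graph_sizes"].items()}
    spec = CorpusSpec(**spec_doc)
    splits = {}
    for name in ("train", "val", "test"):
        pairs = []
        with open(directory / f"{name}.jsonl", encoding="utf-8") as fh:
            for line in fh:
                doc = json.loads(line)
                pairs.append(TrainingPair(
                    motif_from_dict(doc["motif"]),
                    _graph_from_jsonable(doc["graph"]),
                    int(doc["label"])))
        splits[name] = pairs
    return Corpus(spec=spec, registry=set(manifest["registry"]), **splits)
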