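"""Cell tables and cellular-community graphs.

A cellular community (CC) is the Delaunay triangulation of the cells in a
region of interest: nodes are cells carrying a cell-type label and their
planar coordinates, edges are triangulation adjacencies.  The CC is the
target graph in which motifs are counted; all per-node work runs on small
"enclosed graphs" — the induced subgraph within a fixed number of hops of a
center cell (hop = 2 throughout the analyses).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

DEFAULT_COLUMNS = ("cell_id", "x", "y", "cell_type")

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
    "build_cc",
    "enclosed_graph",
    "motif_enriched_region",
    "write_graphml",
    "read_graphml",
]


class DegenerateInputError(ValueError):
    """Raised when a point set cannot be triangulated."""


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate (and return) a cell table.

    Requires columns ``cell_id, x, y, cell_type``; ids unique, coordinates
    finite.  Row order is preserved.
    """
    for col in DEFAULT_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table is missing required column {col!r}")
    if cells["cell_id"].duplicated().any():
        dupes = cells.loc[cells["cell_id"].duplicated(), "cell_id"].unique()
        raise ValueError(f"duplicate cell_id values: {list(dupes)[:5]}")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in cell table")
    out = cells.loc[:, list(DEFAULT_COLUMNS)].copy()
    out["x"] = out["x"].astype(float)
    out["y"] = out["y"].astype(float)
    out["cell_type"] = out["cell_type"].astype(str)
    return out


def read_cell_table(path, column_map: Mapping[str, str] | None = None,
                    sep: str | None = None) -> pd.DataFrame:
    """Read a delimited cell table (header row, UTF-8).

    ``column_map`` renames file columns onto the canonical names
    ``cell_id, x, y, cell_type`` (keys = file column names).
    """
    df = pd.read_csv(path, sep=sep, engine="python", encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    return validate_cell_table(df)


def write_cell_table(cells: pd.DataFrame, path, sep: str = ",") -> None:
    validate_cell_table(cells).to_csv(path, sep=sep, index=False)


def build_cc(cells: pd.DataFrame, max_edge_length: float | None = None) -> nx.Graph:
    """Delaunay-triangulate a cell table into a cellular-community graph.

    Nodes are the ``cell_id`` values with attributes ``cell_type``, ``x``,
    ``y``; edges are exactly the Delaunay edges of the (x, y) point set.
    ``max_edge_length`` optionally drops edges longer than the cutoff
    (off by default: the raw triangulation is kept).
    """
    cells = validate_cell_table(cells)
    n = len(cells)
    if n < 3:
        raise DegenerateInputError(f"need at least 3 cells, got {n}")
    pts = cells[["x", "y"]].to_numpy(dtype=float)
    dup_mask = pd.DataFrame(pts).duplicated(keep=False).to_numpy()
    if dup_mask.any():
        dupes = cells.loc[dup_mask, "cell_id"].tolist()
        raise ValueError(f"duplicate coordinates for cells: {dupes[:10]}")
    try:
        tri = Delaunay(pts)
    except Exception as e:  # qhull rejects collinear inputs
        raise DegenerateInputError(f"triangulation failed: {e}") from e
    if tri.simplices.size == 0:
        raise DegenerateInputError("all points collinear; no triangulation exists")

    ids = cells["cell_id"].tolist()
    g = nx.Graph()
    for i, row in enumerate(cells.itertuples(index=False)):
        g.add_node(ids[i], cell_type=row.cell_type, x=float(row.x), y=float(row.y))
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                u, v = int(simplex[a]), int(simplex[b])
                if max_edge_length is not None:
                    if np.hypot(*(pts[u] - pts[v])) > max_edge_length:
                        continue
                g.add_edge(ids[u], ids[v])
    return g


def enclosed_graph(G: nx.Graph, v, hop: int = 2) -> nx.Graph:
    """Node-induced subgraph on all nodes within ``hop`` edges of ``v``.

    The default radius of 2 keeps enclosed graphs comparable in size to the
    motifs being matched.
    """
    if v not in G:
        raise KeyError(f"node {v!r} not in graph")
    if hop < 0:
        raise ValueError("hop must be non-negative")
    reach = nx.single_source_shortest_path_length(G, v, cutoff=hop)
    sub = G.subgraph(reach.keys()).copy()
    sub.graph["center"] = v
    sub.graph["hop"] = hop
    return sub


def motif_enriched_region(G: nx.Graph, embeddings: Iterable[Sequence], hops: int = 3) -> set:
    """Union of motif embedding nodes expanded by ``hops`` graph steps.

    The complement of the returned set is the complementary non-motif
    region used in differential comparisons.
    """
    frontier: set = set()
    for emb in embeddings:
        for node in emb:
            if node not in G:
                raise KeyError(f"embedding node {node!r} not in graph")
            frontier.add(node)
    region = set(frontier)
    for _ in range(hops):
        nxt = set()
        for u in frontier:
            nxt.update(G.neighbors(u))
        nxt -= region
        if not nxt:
            break
        region |= nxt
        frontier = nxt
    return region


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)


def read_graphml(path) -> nx.Graph:
    g = nx.read_graphml(path)
    for _, data in g.nodes(data=True):
        if "x" in data:
            data["x"] = float(data["x"])
        if "y" in data:
            data["y"] = float(data["y"])
    return g
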