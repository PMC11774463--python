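"""Cell tables, Delaunay graphs, enclosed graphs, motif regions."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ccmotif.graph import (DegenerateInputError, build_cc, enclosed_graph,
                           motif_enriched_region, read_cell_table,
                           read_graphml, write_cell_table, write_graphml)
from ccmotif.synthetic import random_cell_table


# -- cell table io ---------------------------------------------------------


def test_read_minimal_table(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text("cell_id,x,y,cell_type\nc1,0.0,0.0,A\n")
    cells = read_cell_table(p)
    assert len(cells) == 1
    assert cells.loc[0, "cell_type"] == "A"


def test_missing_column_is_named_in_error(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text("cell_id,x,y\nc1,0.0,0.0\n")
    with pytest.raises(ValueError, match="cell_type"):
        read_cell_table(p)


def test_duplicate_ids_rejected(tmp_path):
    p = tmp_path / "cells.csv"
    p.write_text("cell_id,x,y,cell_type\nc1,0,0,A\nc1,1,1,B\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_cell_table(p)


def test_column_map_renames(tmp_path):
    p = tmp_path / "cells.tsv"
    p.write_text("id\tX\tY\ttype\nc1\t0\t0\tA\nc2\t1\t0\tB\n")
    cells = read_cell_table(p, column_map={"id": "cell_id", "X": "x",
                                           "Y": "y", "type": "cell_type"})
    assert list(cells["cell_type"]) == ["A", "B"]


def test_cell_table_round_trip(tmp_path, rng):
    cells = random_cell_table(50, 4, rng)
    path = tmp_path / "t.csv"
    write_cell_table(cells, path)
    back = read_cell_table(path)
    pd.testing.assert_frame_equal(back, cells, check_exact=False)


# -- triangulation ---------------------------------------------------------


def test_three_points_make_a_triangle(triangle_cells):
    G = build_cc(triangle_cells)
    assert G.number_of_nodes() == 3
    assert G.number_of_edges() == 3
    assert G.nodes["a"]["cell_type"] == "A"


def test_too_few_or_collinear_points_degenerate(triangle_cells):
    with pytest.raises(DegenerateInputError):
        build_cc(triangle_cells.iloc[:2])
    collinear = pd.DataFrame({"cell_id": list("abcd"),
                              "x": [0.0, 1.0, 2.0, 3.0],
                              "y": [0.0, 0.0, 0.0, 0.0],
                              "cell_type": ["A"] * 4})
    with pytest.raises(DegenerateInputError):
        build_cc(collinear)


def test_duplicate_coordinates_listed(triangle_cells):
    dup = triangle_cells.copy()
    dup.loc[2, ["x", "y"]] = [0.0, 0.0]
    with pytest.raises(ValueError, match="duplicate coordinates"):
        build_cc(dup)


def _circumcircle(p1, p2, p3):
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    r = np.hypot(ax - ux, ay - uy)
    return (ux, uy), r


def _point_in_triangle(p, a, b, c):
    def sign(p1, p2, p3):
        return (p1[0] - p3[0]) * (p2[1] - p3[1]) - (p2[0] - p3[0]) * (p1[1] - p3[1])
    d1, d2, d3 = sign(p, a, b), sign(p, b, c), sign(p, c, a)
    neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (neg and pos)


def test_delaunay_empty_circumcircle_property(rng):
    """Independent geometric check: every facial triangle (a 3-clique whose
    interior holds no other cell) has a circumcircle empty of all other
    cells — the defining Delaunay property."""
    cells = random_cell_table(30, 2, rng)
    G = build_cc(cells)
    pos = {r.cell_id: (r.x, r.y) for r in cells.itertuples()}
    from ccmotif.occurrence import triangle_iter
    pts = np.array([[r.x, r.y] for r in cells.itertuples()])
    checked = 0
    for tri in triangle_iter(G):
        corners = [pos[t] for t in tri]
        others = [cid for cid in pos if cid not in tri]
        if any(_point_in_triangle(pos[o], *corners) for o in others):
            continue  # non-facial clique: no circumcircle guarantee
        checked += 1
        (cx, cy), r = _circumcircle(*corners)
        dists = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        inside = dists < r - 1e-9
        names = set(cells["cell_id"][inside])
        assert not (names - set(tri))
    assert checked >= 20  # a 30-point triangulation has dozens of faces


def test_planarity_bound_and_connectivity(rng):
    cells = random_cell_table(100, 3, rng)
    G = build_cc(cells)
    assert G.number_of_edges() <= 3 * 100 - 6
    assert nx.is_connected(G)


def test_build_cc_deterministic(rng):
    cells = random_cell_table(80, 3, rng)
    e1 = set(build_cc(cells).edges())
    e2 = set(build_cc(cells.copy()).edges())
    assert e1 == e2


def test_max_edge_length_filter(triangle_cells):
    G = build_cc(triangle_cells, max_edge_length=1.05)
    assert G.number_of_edges() == 1  # only the unit-length edge survives


# -- enclosed graphs -------------------------------------------------------


def test_enclosed_graph_hop_zero_and_saturation(medium_graph):
    v = next(iter(medium_graph.nodes()))
    zero = enclosed_graph(medium_graph, v, hop=0)
    assert set(zero.nodes()) == {v} and zero.number_of_edges() == 0
    full = enclosed_graph(medium_graph, v, hop=10**6)
    assert set(full.nodes()) == set(medium_graph.nodes())


def test_enclosed_graph_matches_bfs_and_is_induced(medium_graph):
    for v in list(medium_graph.nodes())[:10]:
        sub = enclosed_graph(medium_graph, v, hop=2)
        bfs = {v}
        frontier = {v}
        for _ in range(2):
            frontier = {w for u in frontier
                        for w in medium_graph.neighbors(u)} - bfs
            bfs |= frontier
        assert set(sub.nodes()) == bfs
        for u in sub.nodes():
            for w in sub.nodes():
                assert sub.has_edge(u, w) == medium_graph.has_edge(u, w)


def test_enclosed_graph_monotone_in_hop(medium_graph):
    v = next(iter(medium_graph.nodes()))
    prev = set()
    for hop in range(5):
        cur = set(enclosed_graph(medium_graph, v, hop).nodes())
        assert prev <= cur
        prev = cur


def test_enclosed_graph_missing_node_raises(medium_graph):
    with pytest.raises(KeyError):
        enclosed_graph(medium_graph, "no-such-node")


# -- motif regions ---------------------------------------------------------


def test_motif_region_empty_and_no_expansion(medium_graph):
    assert motif_enriched_region(medium_graph, []) == set()
    nodes = list(medium_graph.nodes())[:3]
    assert motif_enriched_region(medium_graph, [nodes], hops=0) == set(nodes)


def test_motif_region_equals_bfs_union(medium_graph):
    emb = [list(medium_graph.nodes())[:3], list(medium_graph.nodes())[10:12]]
    got = motif_enriched_region(medium_graph, emb, hops=3)
    expected = set()
    for nodes in emb:
        for v in nodes:
            expected |= set(nx.single_source_shortest_path_length(
                medium_graph, v, cutoff=3))
    assert got == expected


# -- graphml ---------------------------------------------------------------


def test_graphml_round_trip(tmp_path, medium_graph):
    p = tmp_path / "g.graphml"
    write_graphml(medium_graph, p)
    back = read_graphml(p)
    assert set(map(str, medium_graph.nodes())) == set(back.nodes())
    assert back.number_of_edges() == medium_graph.number_of_edges()
    n0 = sorted(medium_graph.nodes(), key=str)[0]
    assert back.nodes[str(n0)]["cell_type"] == medium_graph.nodes[n0]["cell_type"]
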