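"""Positional encoding and the presence classifier."""

import networkx as nx
import numpy as np
import pytest

from ccmotif.nn import (SubgraphPresenceClassifier, _encode_graph,
                        _init_params, compute_pe, embed_graph)
from ccmotif.synthetic import CorpusSpec, generate_training_corpus, \
    random_triangulated_graph

TRI = [(0, 1), (1, 2), (0, 2)]


def _labeled(labels, edges):
    g = nx.Graph()
    for i, lab in enumerate(labels):
        g.add_node(f"n{i}", cell_type=lab)
    g.add_edges_from((f"n{u}", f"n{v}") for u, v in edges)
    return g


# -- positional encoding ---------------------------------------------------


def test_pe_on_path_anchors_at_first_diameter_endpoint():
    g = _labeled(["A", "B", "C"], [(0, 1), (1, 2)])
    pe = compute_pe(g)
    assert pe.anchor == "n0"
    assert pe.as_array(["n0", "n1", "n2"]).tolist() == [0.0, 1.0, 2.0]


def test_pe_singleton():
    g = _labeled(["A"], [])
    pe = compute_pe(g)
    assert pe.distances == {"n0": 0}


def test_pe_matches_independent_bfs():
    g = random_triangulated_graph(40, 3, seed=8)
    pe = compute_pe(g)
    # plain-queue BFS, no networkx
    adj = {n: set(g.neighbors(n)) for n in g.nodes()}
    dist = {pe.anchor: 0}
    queue = [pe.anchor]
    while queue:
        nxt = []
        for u in queue:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        queue = nxt
    assert pe.distances == dist
    ecc = max(dist.values())
    assert max(nx.eccentricity(g).values()) == \
        nx.eccentricity(g, v=pe.anchor)  # anchor is a diameter endpoint


def test_pe_rejects_disconnected():
    g = _labeled(["A", "B"], [])
    with pytest.raises(ValueError):
        compute_pe(g)


# -- embeddings ------------------------------------------------------------


def _manual_model(n_layers=1, hidden=4, n_labels=2, seed=0):
    rng = np.random.default_rng(seed)
    return _init_params(rng, n_layers, n_labels, hidden)


def test_embedding_permutation_invariance():
    g1 = _labeled(["A", "B", "A", "B"], TRI + [(1, 3), (2, 3)])
    g2 = nx.Graph()
    for n in reversed(list(g1.nodes())):
        g2.add_node(n, **g1.nodes[n])
    g2.add_edges_from(reversed(list(g1.edges())))
    params = _manual_model(n_layers=2)
    li = {"A": 0, "B": 1}
    v1 = embed_graph(g1, params, li)
    v2 = embed_graph(g2, params, li)
    assert np.allclose(v1, v2)


def test_pe_scale_zero_equals_zeroed_pe_vector():
    """Wiring check: disabling the PE term must equal feeding an all-zero
    encoding, i.e. the model reduces to a plain GIN."""
    g = random_triangulated_graph(12, 2, seed=3)
    params = _manual_model(n_layers=3)
    li = {"t00": 0, "t01": 1}
    plain = embed_graph(g, params, li, pe_scale=0.0)
    zeroed = embed_graph(g, params, li, pe_scale=1.0,
                         pe=np.zeros(g.number_of_nodes()))
    assert np.allclose(plain, zeroed)
    with_pe = embed_graph(g, params, li, pe_scale=1.0)
    assert not np.allclose(plain, with_pe)


def test_embedding_hand_computed_two_node_graph():
    """One layer, epsilon 0, hand-picked weights on a 2-node graph: the
    aggregated message is own + neighbor features + a*PE, then the MLP with
    per-node layer normalization and max+mean pooling — recomputed here
    step by step with plain numpy."""
    g = _labeled(["A", "B"], [(0, 1)])
    li = {"A": 0, "B": 1}
    hidden = 2
    rng = np.random.default_rng(1)
    W1 = rng.normal(size=(2, hidden))
    W2 = rng.normal(size=(hidden, hidden))
    params = {"layers": [{"W1": W1, "b1": np.zeros(hidden),
                          "W2": W2, "b2": np.zeros(hidden)}],
              "Wc1": np.zeros((8 * hidden, hidden)),
              "bc1": np.zeros(hidden), "wc2": np.zeros(hidden), "bc2": 0.0}
    a = 0.5
    X = np.eye(2)                       # rows: n0 (A), n1 (B)
    pe = np.array([0.0, 1.0])           # anchor n0
    Z = X + X[::-1] + a * pe[:, None]   # own + single neighbor + PE

    def ln(u):
        mu = u.mean(-1, keepdims=True)
        sd = np.sqrt(((u - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
        return (u - mu) / sd

    def lrelu(u):
        return np.where(u > 0, u, 0.01 * u)

    R = lrelu(ln(Z @ W1))
    H = lrelu(R @ W2)
    expected = np.concatenate([H.max(axis=0), H.mean(axis=0)])
    got = embed_graph(g, params, li, epsilon=0.0, pe_scale=a)
    assert np.allclose(got, expected)


def test_unknown_label_rejected():
    g = _labeled(["Z"], [])
    with pytest.raises(ValueError, match="alphabet"):
        _encode_graph(g, {"A": 0})


# -- training --------------------------------------------------------------


@pytest.fixture(scope="module")
def tiny_corpus():
    spec = CorpusSpec(motif_sizes=(3,), topologies_per_size=1,
                      node_type_counts=(4,), permutations_per_motif=3,
                      graphs_per_permutation=40, seed=21)
    return generate_training_corpus(spec)


def _xy(pairs):
    return [(p.motif, p.target) for p in pairs], [p.label for p in pairs]


def test_training_reduces_loss(tiny_corpus):
    X, y = _xy(tiny_corpus.train)
    clf = SubgraphPresenceClassifier(epochs=8, hidden_dim=16, n_layers=2,
                                     random_state=0)
    clf.fit(X, y)
    assert clf.history_[-1] < clf.history_[0]
    assert hasattr(clf, "best_val_mcc_")


def test_training_seeded_bitwise_determinism(tiny_corpus):
    X, y = _xy(tiny_corpus.train[:80])
    runs = []
    for _ in range(2):
        clf = SubgraphPresenceClassifier(epochs=3, hidden_dim=8, n_layers=2,
                                         random_state=5)
        clf.fit(X, y)
        runs.append(clf.history_)
    assert runs[0] == runs[1]


def test_single_class_training_rejected(tiny_corpus):
    X, y = _xy([p for p in tiny_corpus.train if p.label == 1][:20])
    clf = SubgraphPresenceClassifier(epochs=1)
    with pytest.raises(ValueError, match="both classes"):
        clf.fit(X, y)


def test_prediction_contracts(tiny_corpus):
    X, y = _xy(tiny_corpus.train)
    clf = SubgraphPresenceClassifier(epochs=4, hidden_dim=16, n_layers=2,
                                     random_state=0)
    clf.fit(X, y)
    proba = clf.predict_proba(X[:10])
    assert proba.shape == (10, 2)
    assert np.all((proba >= 0) & (proba <= 1))
    assert np.allclose(proba.sum(axis=1), 1.0)
    p1, l1 = clf.predict_presence(X[0][1], X[0][0])
    p2, l2 = clf.predict_presence(X[0][1], X[0][0])
    assert p1 == p2 and l1 == l2
    # prediction invariance under node reordering of the target
    g = X[0][1]
    g2 = nx.Graph()
    for n in reversed(list(g.nodes())):
        g2.add_node(n, **g.nodes[n])
    g2.add_edges_from(g.edges())
    assert clf.predict_presence(g2, X[0][0])[0] == pytest.approx(p1)


def test_unfitted_predict_raises():
    clf = SubgraphPresenceClassifier()
    with pytest.raises(RuntimeError):
        clf.predict_proba([])


def test_save_load_round_trip(tmp_path, tiny_corpus):
    X, y = _xy(tiny_corpus.train[:80])
    clf = SubgraphPresenceClassifier(epochs=2, hidden_dim=8, n_layers=2,
                                     random_state=0)
    clf.fit(X, y)
    path = tmp_path / "model.npz"
    clf.save(path)
    back = SubgraphPresenceClassifier.load(path)
    assert np.allclose(back.predict_proba(X[:5]), clf.predict_proba(X[:5]))
    with pytest.raises(ValueError, match="alphabet"):
        SubgraphPresenceClassifier.load(path, expected_alphabet=["x", "y"])


def test_sklearn_param_protocol():
    clf = SubgraphPresenceClassifier(hidden_dim=8)
    assert clf.get_params()["hidden_dim"] == 8
    clf.set_params(epochs=3)
    assert clf.epochs == 3
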