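"""Learned presence classifier for motif-in-graph queries.

The classifier decides whether a query motif occurs (as an induced,
label-matching subgraph) inside a small target graph — typically the
2-hop enclosed graph around one cell.  Architecture:

* a shared GIN-style encoder over both query and target: per layer
  ``h_v = MLP((1+eps) h_v + sum_{u in N(v)} h_u + a * PE_v)`` where
  ``PE_v`` is the shortest-path hop distance from an anchor node v0 (an
  endpoint of a longest shortest path, i.e. a graph-diameter endpoint),
  broadcast across hidden channels and scaled by ``a``;
* coordinate-wise max pooling over final node embeddings, concatenated
  with mean pooling, for the query motif's graph vector;
* a node-wise matching head: the motif vector is compared against every
  target-node embedding (concatenation with elementwise product and
  squared difference, through two linear layers); per-node match scores
  aggregate by a masked log-sum-exp — a smooth "some neighborhood
  matches" — and a sigmoid gives the presence probability.

Trained by minimizing binary cross-entropy with Adam.  Implemented
directly on numpy with hand-derived gradients; everything is seeded and
single-threaded deterministic.  The estimator follows the scikit-learn
protocol (``fit`` / ``predict`` / ``predict_proba`` / ``get_params``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import matthews_corrcoef
from threadpoolctl import threadpool_limits

from .motif import Motif

__all__ = ["PEVector", "compute_pe", "SubgraphPresenceClassifier", "embed_graph"]


# -- positional encoding ---------------------------------------------------


@dataclass
class PEVector:
    """Shortest-path positional encoding anchored at a diameter endpoint."""

    anchor: object
    distances: dict

    def as_array(self, node_order: Sequence) -> np.ndarray:
        return np.array([self.distances[n] for n in node_order], dtype=float)


def compute_pe(g: nx.Graph) -> PEVector:
    """Hop distances from v0, an endpoint of a maximum-length shortest path
    (ties broken by smallest node index in sorted order)."""
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph has no positional encoding")
    if not nx.is_connected(g):
        raise ValueError("positional encoding requires a connected graph")
    order = sorted(g.nodes(), key=str)
    ecc = nx.eccentricity(g)
    v0 = max(order, key=lambda n: (ecc[n], -order.index(n)))
    # max() keeps the first of equal keys, so encode tie-break explicitly:
    best = max(ecc.values())
    for n in order:
        if ecc[n] == best:
            v0 = n
            break
    dist = nx.single_source_shortest_path_length(g, v0)
    return PEVector(anchor=v0, distances=dict(dist))


# -- encoding graphs to arrays ---------------------------------------------


def _encode_graph(g: nx.Graph, label_index: dict[str, int]):
    order = sorted(g.nodes(), key=str)
    n = len(order)
    T = len(label_index)
    X = np.zeros((n, T))
    for i, node in enumerate(order):
        lab = g.nodes[node]["cell_type"]
        if lab not in label_index:
            raise ValueError(f"cell type {lab!r} outside the model alphabet")
        X[i, label_index[lab]] = 1.0
    A = np.zeros((n, n))
    pos = {node: i for i, node in enumerate(order)}
    for u, v in g.edges():
        A[pos[u], pos[v]] = 1.0
        A[pos[v], pos[u]] = 1.0
    pe = compute_pe(g).as_array(order)
    return A, X, pe


def _pack(batch):
    """Pad a list of (A, X, pe) to common node count; returns batched
    arrays plus a node mask."""
    B = len(batch)
    N = max(a.shape[0] for a, _, _ in batch)
    T = batch[0][1].shape[1]
    A = np.zeros((B, N, N))
    X = np.zeros((B, N, T))
    pe = np.zeros((B, N, 1))
    mask = np.zeros((B, N), dtype=bool)
    for b, (a, x, p) in enumerate(batch):
        n = a.shape[0]
        A[b, :n, :n] = a
        X[b, :n, :] = x
        pe[b, :n, 0] = p
        mask[b, :n] = True
    return A, X, pe, mask


# -- parameters ------------------------------------------------------------


def _glorot(rng, shape):
    # halved Glorot: sum aggregation over triangulation degrees (~6) grows
    # activations layer over layer; the damping keeps initial logits small
    limit = 0.5 * np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _init_params(rng, n_layers: int, in_dim: int, hidden: int) -> dict:
    layers = []
    d = in_dim
    for _ in range(n_layers):
        layers.append({
            "W1": _glorot(rng, (d, hidden)), "b1": np.zeros(hidden),
            "W2": _glorot(rng, (hidden, hidden)), "b2": np.zeros(hidden),
        })
        d = hidden
    return {
        "layers": layers,
        "Wm": _glorot(rng, (2 * hidden, hidden)), "bm": np.zeros(hidden),
        "Wc1": _glorot(rng, (4 * hidden, hidden)), "bc1": np.zeros(hidden),
        "wc2": _glorot(rng, (hidden, 1))[:, 0], "bc2": 0.0,
    }


_HEAD_KEYS = ("Wm", "bm", "Wc1", "bc1", "wc2")


def _zeros_like_params(params: dict) -> dict:
    out = {"layers": [], "bc2": 0.0}
    for key in _HEAD_KEYS:
        out[key] = np.zeros_like(params[key])
    for lay in params["layers"]:
        out["layers"].append({k: np.zeros_like(v) for k, v in lay.items()})
    return out


def _copy_params(params: dict) -> dict:
    out = {"layers": [{k: v.copy() for k, v in lay.items()}
                      for lay in params["layers"]],
           "bc2": float(params["bc2"])}
    for key in _HEAD_KEYS:
        out[key] = params[key].copy()
    return out


# -- forward / backward ----------------------------------------------------


_LEAK = 0.01  # leaky-rectifier slope: keeps gradient flow, no dead basin


def _lrelu(x):
    return np.where(x > 0, x, _LEAK * x)


def _lrelu_grad(x):
    return np.where(x > 0, 1.0, _LEAK)


def _ln_fwd(U):
    # per-node layer normalization (no learnable affine); keeps activations
    # bounded under sum aggregation and makes training stable without batch
    # statistics, so inference stays deterministic per sample
    mu = U.mean(axis=-1, keepdims=True)
    xc = U - mu
    inv = 1.0 / np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + 1e-5)
    Un = xc * inv
    return Un, inv


def _ln_bwd(dUn, Un, inv):
    m1 = dUn.mean(axis=-1, keepdims=True)
    m2 = (dUn * Un).mean(axis=-1, keepdims=True)
    return inv * (dUn - m1 - Un * m2)


def _encoder_forward(params, A, X, pe, mask, eps, a):
    caches = []
    H = X
    for lay in params["layers"]:
        Z = (1.0 + eps) * H + A @ H + a * pe
        U = Z @ lay["W1"] + lay["b1"]
        Un, inv1 = _ln_fwd(U)          # normalize once per layer, after
        R = _lrelu(Un)                 # the first linear map
        V = R @ lay["W2"] + lay["b2"]
        Hn = _lrelu(V)
        caches.append((Z, Un, inv1, R, V))
        H = Hn
    neg = np.where(mask[:, :, None], 0.0, -1e30)
    amax = np.argmax(H + neg, axis=1)              # (B, hidden)
    Gmax = np.take_along_axis(H, amax[:, None, :], axis=1)[:, 0, :]
    counts = mask.sum(axis=1, keepdims=True).astype(float)
    Gmean = (H * mask[:, :, None]).sum(axis=1) / counts
    G = np.concatenate([Gmax, Gmean], axis=1)      # (B, 2*hidden)
    return G, H, (caches, amax, H.shape, mask, counts)


def _encoder_backward(params, dG, state, A, eps, grads):
    """Backprop from a pooled graph-vector gradient."""
    caches, amax, shape, mask, counts = state
    hid = shape[-1]
    dGmax, dGmean = dG[:, :hid], dG[:, hid:]
    dH = np.zeros(shape)
    np.put_along_axis(dH, amax[:, None, :], dGmax[:, None, :], axis=1)
    dH += (dGmean / counts)[:, None, :] * mask[:, :, None]
    return _encoder_layers_backward(params, dH, state, A, eps, grads)


def _encoder_layers_backward(params, dH, state, A, eps, grads):
    """Backprop a per-node embedding gradient through the GIN layers."""
    caches = state[0]
    for lay, glay, (Z, Un, inv1, R, V) in zip(
            reversed(params["layers"]), reversed(grads["layers"]),
            reversed(caches)):
        dV = dH * _lrelu_grad(V)
        glay["W2"] += np.einsum("bnh,bnk->hk", R, dV)
        glay["b2"] += dV.sum(axis=(0, 1))
        dR = dV @ lay["W2"].T
        dUn = dR * _lrelu_grad(Un)
        dU = _ln_bwd(dUn, Un, inv1)
        glay["W1"] += np.einsum("bnd,bnh->dh", Z, dU)
        glay["b1"] += dU.sum(axis=(0, 1))
        dZ = dU @ lay["W1"].T
        dH = (1.0 + eps) * dZ + A @ dZ             # A symmetric
    return dH


def _pair_forward(params, packed_g, packed_m, eps, a, drop_mask=None):
    """Node-wise matching head.

    The motif's pooled vector is projected to hidden width and compared
    against every target-node embedding (concatenation + product +
    squared difference through a small MLP); per-node match scores are
    aggregated by a masked log-sum-exp — a smooth "does any neighborhood
    match" — and squashed by the sigmoid.
    """
    Ag, Xg, peg, mg = packed_g
    Am, Xm, pem, mm = packed_m
    _, Hg, sg = _encoder_forward(params, Ag, Xg, peg, mg, eps, a)
    Gm, _, sm = _encoder_forward(params, Am, Xm, pem, mm, eps, a)
    mproj = Gm @ params["Wm"] + params["bm"]        # (B, hidden)
    M = mproj[:, None, :]
    diff = Hg - M
    Feat = np.concatenate(
        [Hg, np.broadcast_to(M, Hg.shape), Hg * M, diff ** 2], axis=2)
    U1 = Feat @ params["Wc1"] + params["bc1"]       # (B, N, hidden)
    R1 = _lrelu(U1)
    if drop_mask is not None:           # inverted dropout, training only
        R1 = R1 * drop_mask[:, None, :]
    scores = R1 @ params["wc2"] + params["bc2"]     # (B, N)
    masked = np.where(mg, scores, -1e30)
    mx = masked.max(axis=1)
    ex = np.exp(masked - mx[:, None]) * mg
    S = ex.sum(axis=1)
    s = mx + np.log(S)
    p = 1.0 / (1.0 + np.exp(-s))
    softw = ex / S[:, None]
    return p, (sg, sm, Gm, mproj, Hg, Feat, U1, R1, softw, drop_mask)


def _pair_backward(params, p, y, state, packed_g, packed_m, eps, a, grads):
    sg, sm, Gm, mproj, Hg, Feat, U1, R1, softw, drop_mask = state
    B = len(y)
    ds = (p - y) / B
    dscores = ds[:, None] * softw                   # zero on padded nodes
    grads["bc2"] += dscores.sum()
    grads["wc2"] += np.einsum("bnh,bn->h", R1, dscores)
    dR1 = dscores[:, :, None] * params["wc2"][None, None, :]
    if drop_mask is not None:
        dR1 = dR1 * drop_mask[:, None, :]
    dU1 = dR1 * _lrelu_grad(U1)
    grads["Wc1"] += np.einsum("bnf,bnh->fh", Feat, dU1)
    grads["bc1"] += dU1.sum(axis=(0, 1))
    dFeat = dU1 @ params["Wc1"].T
    hid = Hg.shape[-1]
    d1 = dFeat[:, :, :hid]
    d2 = dFeat[:, :, hid:2 * hid]
    d3 = dFeat[:, :, 2 * hid:3 * hid]
    d4 = dFeat[:, :, 3 * hid:]
    M = mproj[:, None, :]
    diff = Hg - M
    dHg = d1 + d3 * M + 2.0 * diff * d4
    dM = d2 + d3 * Hg - 2.0 * diff * d4
    dmproj = dM.sum(axis=1)
    grads["Wm"] += Gm.T @ dmproj
    grads["bm"] += dmproj.sum(axis=0)
    dGm = dmproj @ params["Wm"].T
    _encoder_layers_backward(params, dHg, sg, packed_g[0], eps, grads)
    _encoder_backward(params, dGm, sm, packed_m[0], eps, grads)


def _clip_grads(grads, max_norm):
    total = grads["bc2"] ** 2
    arrays = [grads[k] for k in _HEAD_KEYS]
    for lay in grads["layers"]:
        arrays.extend(lay.values())
    for a in arrays:
        total += float(np.sum(a * a))
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / norm
        for a in arrays:
            a *= scale
        grads["bc2"] *= scale
    return norm


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.t = 0
        self.m = _zeros_like_params(params)
        self.v = _zeros_like_params(params)

    def _step_one(self, p, g, m, v, decay=0.0):
        b1, b2, eps = 0.9, 0.999, 1e-8
        m[...] = b1 * m + (1 - b1) * g
        v[...] = b2 * v + (1 - b2) * g * g
        mh = m / (1 - 0.9 ** self.t)
        vh = v / (1 - 0.999 ** self.t)
        p -= self.lr * (mh / (np.sqrt(vh) + eps) + decay * p)

    def step(self, params, grads, weight_decay=0.0):
        self.t += 1
        for lay, glay, mlay, vlay in zip(params["layers"], grads["layers"],
                                         self.m["layers"], self.v["layers"]):
            for key in lay:
                decay = weight_decay if key.startswith("W") else 0.0
                self._step_one(lay[key], glay[key], mlay[key], vlay[key],
                               decay)
        for key in _HEAD_KEYS:
            decay = weight_decay if key.startswith("W") else 0.0
            self._step_one(params[key], grads[key], self.m[key], self.v[key],
                           decay)
        # scalar bias
        b1, b2 = 0.9, 0.999
        self.m["bc2"] = b1 * self.m["bc2"] + (1 - b1) * grads["bc2"]
        self.v["bc2"] = b2 * self.v["bc2"] + (1 - b2) * grads["bc2"] ** 2
        mh = self.m["bc2"] / (1 - b1 ** self.t)
        vh = self.v["bc2"] / (1 - b2 ** self.t)
        params["bc2"] -= self.lr * mh / (np.sqrt(vh) + 1e-8)


# -- public estimator ------------------------------------------------------


def embed_graph(g: nx.Graph, params: dict, label_index: dict[str, int],
                epsilon: float = 0.0, pe_scale: float = 1.0,
                pe: np.ndarray | None = None) -> np.ndarray:
    """Graph-level embedding vector for a single graph under fixed weights.

    ``pe`` overrides the computed positional encoding (useful for
    ablation); deterministic given the weights.
    """
    A, X, p = _encode_graph(g, label_index)
    if pe is not None:
        p = np.asarray(pe, dtype=float)
    packed = _pack([(A, X, p)])
    G, _, _ = _encoder_forward(params, *packed, epsilon, pe_scale)
    return G[0]


class SubgraphPresenceClassifier(BaseEstimator, ClassifierMixin):
    """GIN + shortest-distance-PE binary classifier for motif presence.

    Parameters
    ----------
    n_layers, hidden_dim:
        Depth and width of the shared encoder (each layer a 2-layer MLP).
    epsilon:
        Fixed self-weighting scalar of the GIN aggregation.
    pe_scale:
        Strength ``a`` of the positional-encoding term; 0 disables PE and
        reduces the model to a plain GIN.
    learning_rate, epochs, batch_size:
        Adam settings; the checkpoint with the best validation MCC is kept.
    lr_decay:
        Multiplicative learning-rate decay per epoch.
    grad_clip:
        Global-norm gradient clipping bound (guards against optimizer
        steps that kill every rectifier at once).
    weight_decay:
        AdamW-style decoupled L2 decay on weight matrices.
    dropout:
        Inverted-dropout rate on the comparison head's hidden layer
        (training only; inference is deterministic).
    n_checkpoints:
        Size of the checkpoint ensemble: predictions average the
        probabilities of the best ``n_checkpoints`` validation-MCC
        epoch checkpoints (1 = classic single best checkpoint).
    n_restarts:
        Independent training restarts (distinct seeded inits); the
        checkpoint ensemble pools the best checkpoints of every restart.
    validation_fraction:
        Held-out fraction split from the training pairs when no explicit
        validation set is passed to :meth:`fit`.
    threshold:
        Probability cutoff for the binary presence call.
    """

    def __init__(self, n_layers: int = 3, hidden_dim: int = 64,
                 epsilon: float = 0.0, pe_scale: float = 0.5,
                 learning_rate: float = 1e-3, epochs: int = 100,
                 batch_size: int = 64, lr_decay: float = 0.985,
                 grad_clip: float = 2.0, weight_decay: float = 1e-4,
                 dropout: float = 0.3, n_checkpoints: int = 3,
                 n_restarts: int = 1, threshold: float = 0.5,
                 validation_fraction: float = 0.1, random_state: int = 0):
        self.n_layers = n_layers
        self.hidden_dim = hidden_dim
        self.epsilon = epsilon
        self.pe_scale = pe_scale
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_decay = lr_decay
        self.grad_clip = grad_clip
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.n_checkpoints = n_checkpoints
        self.n_restarts = n_restarts
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("classifier is not fitted")

    def _encode_pairs(self, pairs):
        encoded = []
        for m, g in pairs:
            gm = m.to_networkx() if isinstance(m, Motif) else m
            encoded.append((_encode_graph(g, self._label_index_),
                            _encode_graph(gm, self._label_index_)))
        return encoded

    @staticmethod
    def build_alphabet(pairs) -> list[str]:
        labels = set()
        for m, g in pairs:
            if isinstance(m, Motif):
                labels.update(m.labels)
            else:
                labels.update(nx.get_node_attributes(m, "cell_type").values())
            labels.update(nx.get_node_attributes(g, "cell_type").values())
        return sorted(labels)

    def _forward_batch(self, encoded, idx, params):
        packed_g = _pack([encoded[i][0] for i in idx])
        packed_m = _pack([encoded[i][1] for i in idx])
        return packed_g, packed_m

    def _predict_encoded(self, encoded, params) -> np.ndarray:
        probs = np.empty(len(encoded))
        for start in range(0, len(encoded), 256):
            idx = range(start, min(start + 256, len(encoded)))
            pg, pm = self._forward_batch(encoded, idx, params)
            p, _ = _pair_forward(params, pg, pm, self.epsilon, self.pe_scale)
            probs[start:start + len(p)] = p
        return probs

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, validation_data=None):
        """Fit on pairs ``X = [(motif, target_graph), ...]`` with binary
        labels ``y``; keeps the epoch checkpoint with best validation MCC.

        Runs under a single BLAS thread so that floating-point reduction
        order — and therefore the fitted weights — are identical across
        machines and load conditions for a fixed ``random_state``.
        """
        with threadpool_limits(limits=1):
            return self._fit(X, y, validation_data)

    def _train_once(self, rng, train_enc, train_y, val_encoded, val_y):
        """One seeded training run; returns its best validation-MCC
        checkpoints (up to ``n_checkpoints``) as (mcc, params) pairs."""
        params = _init_params(rng, self.n_layers,
                              len(self.alphabet_), self.hidden_dim)
        opt = _Adam(params, self.learning_rate)
        checkpoints: list[tuple[float, dict]] = []
        n = len(train_enc)
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pg, pm = self._forward_batch(train_enc, idx, params)
                yb = train_y[idx]
                if self.dropout > 0:
                    keep = 1.0 - self.dropout
                    drop = (rng.random((len(idx), self.hidden_dim)) < keep
                            ) / keep
                else:
                    drop = None
                p, state = _pair_forward(params, pg, pm,
                                         self.epsilon, self.pe_scale,
                                         drop_mask=drop)
                p = np.clip(p, 1e-12, 1 - 1e-12)
                loss = -np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p))
                epoch_loss += loss * len(idx)
                grads = _zeros_like_params(params)
                _pair_backward(params, p, yb, state, pg, pm,
                               self.epsilon, self.pe_scale, grads)
                _clip_grads(grads, self.grad_clip)
                opt.step(params, grads, self.weight_decay)
            opt.lr *= self.lr_decay
            self.history_.append(epoch_loss / n)
            val_p = self._predict_encoded(val_encoded, params)
            if len(np.unique(val_y)) < 2:
                mcc = 0.0
            else:
                mcc = matthews_corrcoef(val_y, (val_p >= self.threshold))
            self.val_mcc_history_.append(mcc)
            worst = min(c[0] for c in checkpoints) if checkpoints else -2.0
            if len(checkpoints) < self.n_checkpoints or mcc > worst:
                checkpoints.append((mcc, _copy_params(params)))
                checkpoints.sort(key=lambda c: -c[0])
                del checkpoints[self.n_checkpoints:]
        return checkpoints

    def _fit(self, X, y, validation_data=None):
        y = np.asarray(y, dtype=float)
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be non-empty and aligned")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data must contain both classes")
        rng = np.random.default_rng(self.random_state)

        self.alphabet_ = self.build_alphabet(X)
        if validation_data is not None:
            extra = self.build_alphabet(validation_data[0])
            self.alphabet_ = sorted(set(self.alphabet_) | set(extra))
        self._label_index_ = {lab: i for i, lab in enumerate(self.alphabet_)}

        encoded = self._encode_pairs(X)
        if validation_data is not None:
            val_encoded = self._encode_pairs(validation_data[0])
            val_y = np.asarray(validation_data[1], dtype=float)
            train_idx = np.arange(len(encoded))
        else:
            order = rng.permutation(len(encoded))
            n_val = max(1, int(round(self.validation_fraction * len(encoded))))
            val_idx, train_idx = order[:n_val], order[n_val:]
            val_encoded = [encoded[i] for i in val_idx]
            val_y = y[val_idx]
        train_y = y[train_idx]
        train_enc = [encoded[i] for i in train_idx]

        self.history_ = []
        self.val_mcc_history_ = []
        pool: list[tuple[float, dict]] = []
        for restart in range(self.n_restarts):
            run_rng = rng if restart == 0 else np.random.default_rng(
                (self.random_state + 9973 * restart) % (2**31))
            pool.extend(self._train_once(run_rng, train_enc, train_y,
                                         val_encoded, val_y))
        pool.sort(key=lambda c: -c[0])
        self.ensemble_ = [params for _, params in pool[:self.n_checkpoints]]
        self.best_val_mcc_, self.params_ = pool[0]
        if len(np.unique(val_y)) >= 2 and len(self.ensemble_) > 1:
            ens_p = self._predict_encoded_ensemble(val_encoded)
            self.best_val_mcc_ = matthews_corrcoef(
                val_y, (ens_p >= self.threshold))
        self.classes_ = np.array([0, 1])
        self.n_iter_ = self.epochs * self.n_restarts
        return self

    def _predict_encoded_ensemble(self, encoded) -> np.ndarray:
        probs = [self._predict_encoded(encoded, params)
                 for params in self.ensemble_]
        return np.mean(probs, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        encoded = self._encode_pairs(X)
        with threadpool_limits(limits=1):
            p = self._predict_encoded_ensemble(encoded)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.threshold).astype(int)

    def predict_presence(self, g: nx.Graph, m: Motif) -> tuple[float, int]:
        """Presence probability and binary call for one (target, motif)."""
        prob = float(self.predict_proba([(m, g)])[0, 1])
        return prob, int(prob >= self.threshold)

    def embed(self, g: nx.Graph, pe: np.ndarray | None = None) -> np.ndarray:
        self._check_fitted()
        return embed_graph(g, self.params_, self._label_index_,
                           self.epsilon, self.pe_scale, pe=pe)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        self._check_fitted()
        arrays = {}
        for j, params in enumerate(self.ensemble_):
            for key in _HEAD_KEYS:
                arrays[f"m{j}_{key}"] = params[key]
            arrays[f"m{j}_bc2"] = np.array(params["bc2"])
            for i, lay in enumerate(params["layers"]):
                for k, v in lay.items():
                    arrays[f"m{j}_layer{i}_{k}"] = v
        meta = {"config": self.get_params(), "alphabet": self.alphabet_,
                "n_layers": self.n_layers, "n_members": len(self.ensemble_)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, expected_alphabet: Sequence[str] | None = None
             ) -> "SubgraphPresenceClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        if expected_alphabet is not None and \
                list(expected_alphabet) != list(meta["alphabet"]):
            raise ValueError("checkpoint alphabet does not match the "
                             "expected cell-type alphabet")
        model = cls(**meta["config"])
        model.alphabet_ = list(meta["alphabet"])
        model._label_index_ = {lab: i for i, lab in enumerate(model.alphabet_)}
        model.ensemble_ = []
        for j in range(meta["n_members"]):
            layers = [{k: data[f"m{j}_layer{i}_{k}"]
                       for k in ("W1", "b1", "W2", "b2")}
                      for i in range(meta["n_layers"])]
            model.ensemble_.append(
                {"layers": layers, "bc2": float(data[f"m{j}_bc2"]),
                 **{key: data[f"m{j}_{key}"] for key in _HEAD_KEYS}})
        model.params_ = model.ensemble_[0]
        model.classes_ = np.array([0, 1])
        return model
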