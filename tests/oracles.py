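"""Independent brute-force oracles used to cross-check the implementation.

Everything here recomputes quantities by a different route than the
package: networkx edge enumeration for the modularity scores, explicit
sorts for nearest neighbours, and exhaustive scans for classification.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


def community_aggregates_nx(a: np.ndarray, labels) -> dict:
    """Per-class w, w_out, s, m, M_out, d by explicit edge enumeration."""
    labels = [str(x) for x in labels]
    g = nx.from_numpy_array(np.asarray(a, dtype=float))
    out: dict = {}
    for cls in sorted(set(labels)):
        members = {i for i, lab in enumerate(labels) if lab == cls}
        w = w_out = m = m_out = 0.0
        for u, v, data in g.edges(data=True):
            inside = (u in members) + (v in members)
            if inside == 2:
                w += data["weight"]
                m += 1
            elif inside == 1:
                w_out += data["weight"]
                m_out += 1
        s = sum(dict(g.degree(members, weight="weight")).values())
        d = sum(dict(g.degree(members)).values())
        out[cls] = {"w": w, "w_out": w_out, "s": s, "m": m, "M_out": m_out, "d": d}
    return out


def lm_oracle(a: np.ndarray, labels) -> float:
    agg = community_aggregates_nx((np.asarray(a) > 0).astype(float), labels)
    total = 0.0
    for v in agg.values():
        big_m = v["m"] + v["M_out"]
        if big_m > 0:
            total += v["m"] / big_m - (v["d"] / (2 * big_m)) ** 2
    return total


def wlm_oracle(a: np.ndarray, labels) -> float:
    agg = community_aggregates_nx(a, labels)
    total = 0.0
    for v in agg.values():
        big_w = v["w"] + v["w_out"]
        if big_w > 0:
            total += v["w"] / big_w - (v["s"] / (2 * big_w)) ** 2
    return total


def wlms_oracle(a: np.ndarray, labels) -> float:
    agg = community_aggregates_nx(a, labels)
    return sum(
        v["w"] / (v["w"] + v["w_out"])
        for v in agg.values()
        if v["w"] + v["w_out"] > 0
    )


def knn_oracle(sq: np.ndarray, k: int) -> list[tuple[int, ...]]:
    """k nearest others per row by (distance, index) sort."""
    m = sq.shape[0]
    sets = []
    for i in range(m):
        order = sorted((j for j in range(m) if j != i), key=lambda j: (sq[i, j], j))
        sets.append(tuple(order[:k]))
    return sets


def union_knn_affinity_oracle(points: np.ndarray, k: int) -> np.ndarray:
    """Affinity matrix via the union k-NN rule, built edge by edge."""
    points = np.atleast_2d(points)
    m = points.shape[0]
    sq = np.array(
        [[np.sum((points[i] - points[j]) ** 2) for j in range(m)] for i in range(m)]
    )
    nbrs = knn_oracle(sq, k)
    a = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            if i != j and (j in nbrs[i] or i in nbrs[j]):
                a[i, j] = np.exp(-np.sqrt(sq[i, j]))
    return a


def one_nn_oracle(train_x, train_y, test_x):
    """Exhaustive nearest-training-point scan with index tie-break."""
    train_x = np.atleast_2d(train_x)
    test_x = np.atleast_2d(test_x)
    preds = []
    for t in test_x:
        best_i, best_d = 0, np.inf
        for i, row in enumerate(train_x):
            d = float(np.sum((t - row) ** 2))
            if d < best_d:
                best_i, best_d = i, d
        preds.append(train_y[best_i])
    return np.asarray(preds, dtype=object)


def random_labelled_graph(rng: np.random.Generator, m: int, n_classes: int):
    """A random symmetric weighted graph with cyclic class labels."""
    mask = rng.random((m, m)) < 0.5
    weights = rng.random((m, m))
    a = np.triu(mask * weights, k=1)
    a = a + a.T
    labels = tuple(f"c{i % n_classes}" for i in range(m))
    return a, labels
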