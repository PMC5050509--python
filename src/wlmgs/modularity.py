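"""Community weights and the three modularity scores.

Communities are always the given class labels — never detected. Three
quality functions are computed over the weighted sample graph:

* ``LM``     — unweighted local modularity,
  sum over classes of  m_k/M_k - (d_k/(2 M_k))^2,
  where m_k counts internal edges, M_k internal plus boundary edges of
  class k, and d_k the total degree of class-k nodes.
* ``WLM``    — its weighted analogue with edge weights and node strengths,
  sum over classes of  w_k/W_k - (s_k/(2 W_k))^2.
* ``WLM^s``  — the simplified score  sum over classes of  w_k/(w_k + w_k_out):
  the fraction of each class's incident edge weight that stays inside the
  class. This is the selection objective; LM and WLM are diagnostics.

Classes with no incident edges (W_k = 0) contribute 0 so degenerate folds
with singleton classes never produce NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import LabeledDataset
from .sample_graph import WeightedSampleGraph, build_wsg

__all__ = [
    "CommunityWeights",
    "ModularityScore",
    "community_weights",
    "local_modularity",
    "weight_local_modularity",
    "wlm_s",
    "wlms_for_subset",
]


@dataclass(frozen=True)
class CommunityWeights:
    """Per-class edge-weight aggregates of a labelled weighted graph.

    For each class k: ``w`` is the summed weight of internal edges (both
    endpoints in k, each edge counted once), ``w_out`` the summed weight
    of boundary edges (exactly one endpoint in k; a boundary edge is
    counted once in each adjacent class's w_out), ``W = w + w_out``, and
    ``s`` the summed node strength over class-k samples, satisfying
    s = 2 w + w_out. ``m``, ``M``, ``d`` are the unweighted analogues
    obtained by replacing every positive weight with 1.
    """

    classes: tuple[str, ...]
    w: np.ndarray
    w_out: np.ndarray
    s: np.ndarray
    m: np.ndarray
    M_out: np.ndarray
    d: np.ndarray

    @property
    def W(self) -> np.ndarray:
        return self.w + self.w_out

    @property
    def M(self) -> np.ndarray:
        return self.m + self.M_out

    def to_dict(self) -> dict:
        return {
            cls: {
                "w": float(self.w[i]),
                "w_out": float(self.w_out[i]),
                "W": float(self.W[i]),
                "s": float(self.s[i]),
                "m": float(self.m[i]),
                "M": float(self.M[i]),
                "d": float(self.d[i]),
            }
            for i, cls in enumerate(self.classes)
        }


@dataclass(frozen=True)
class ModularityScore:
    """A modularity value with its per-class term breakdown."""

    value: float
    terms: dict[str, float]
    kind: str

    def to_dict(self) -> dict:
        return {"kind": self.kind, "value": self.value, "terms": dict(self.terms)}


def _aggregate(a: np.ndarray, labels: np.ndarray, classes: tuple[str, ...]):
    """Internal / boundary / strength sums for one affinity matrix."""
    w = np.zeros(len(classes))
    w_out = np.zeros(len(classes))
    s = np.zeros(len(classes))
    for i, cls in enumerate(classes):
        in_k = labels == cls
        block = a[np.ix_(in_k, in_k)]
        w[i] = block.sum() / 2.0  # symmetric: each internal edge twice
        w_out[i] = a[np.ix_(in_k, ~in_k)].sum()
        s[i] = a[in_k].sum()
    return w, w_out, s


def community_weights(
    graph: WeightedSampleGraph, labels: Sequence[str]
) -> CommunityWeights:
    """Aggregate edge weights of each class and its boundary."""
    labels = np.asarray([str(x) for x in labels], dtype=object)
    if labels.shape[0] != graph.n_samples:
        raise ValueError(
            f"{labels.shape[0]} labels for {graph.n_samples} graph nodes"
        )
    classes = tuple(sorted(set(labels)))
    a = graph.affinity
    w, w_out, s = _aggregate(a, labels, classes)
    m, M_out, d = _aggregate((a > 0).astype(float), labels, classes)
    return CommunityWeights(classes, w, w_out, s, m, M_out, d)


def _lm_form(internal, total, degree, classes, kind) -> ModularityScore:
    """sum_k internal/total - (degree/(2 total))^2, empty classes -> 0."""
    terms: dict[str, float] = {}
    for i, cls in enumerate(classes):
        if total[i] == 0.0:
            terms[cls] = 0.0
        else:
            terms[cls] = float(
                internal[i] / total[i] - (degree[i] / (2.0 * total[i])) ** 2
            )
    return ModularityScore(float(sum(terms.values())), terms, kind)


def local_modularity(
    graph: WeightedSampleGraph, labels: Sequence[str]
) -> ModularityScore:
    """Unweighted local modularity LM (positive weights treated as 1)."""
    cw = community_weights(graph, labels)
    return _lm_form(cw.m, cw.M, cw.d, cw.classes, "LM")


def weight_local_modularity(
    graph: WeightedSampleGraph, labels: Sequence[str]
) -> ModularityScore:
    """Weight local modularity WLM."""
    cw = community_weights(graph, labels)
    return _lm_form(cw.w, cw.W, cw.s, cw.classes, "WLM")


def wlm_s(graph: WeightedSampleGraph, labels: Sequence[str]) -> ModularityScore:
    """Simplified weight local modularity WLM^s = sum_k w_k / (w_k + w_k_out).

    Each term lies in [0, 1], so the value lies in [0, C]; it reaches C
    exactly when no between-class edge exists (and every class has at
    least one internal edge).
    """
    cw = community_weights(graph, labels)
    terms = {
        cls: 0.0 if cw.W[i] == 0.0 else float(cw.w[i] / cw.W[i])
        for i, cls in enumerate(cw.classes)
    }
    return ModularityScore(float(sum(terms.values())), terms, "WLM^s")


def wlms_for_subset(dataset: LabeledDataset, subset: Sequence[int], k: int) -> float:
    """WLM^s of the weighted sample graph built on a gene subset.

    The selection algorithm's single scoring entry point.
    """
    graph = build_wsg(dataset.matrix, subset, k)
    return wlm_s(graph, dataset.labels).value
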