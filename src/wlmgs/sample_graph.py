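"""Weighted sample graph (WSG) construction.

Nodes are samples; an undirected edge joins i and j whenever i is among
the k nearest neighbours of j *or* vice versa (the union rule), with
weight exp(-d(i, j)) where d is the Euclidean distance in the current
gene subspace. Squared distances are maintained incrementally so the
forward search can grow the subset one gene at a time at O(m^2) per
candidate instead of O(|subset| * m^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data_model import ExpressionMatrix

__all__ = [
    "DistanceState",
    "WeightedSampleGraph",
    "squared_distances",
    "extend_distances",
    "knn_sets",
    "build_wsg",
    "wsg_from_distances",
    "write_edge_list",
]


@dataclass(frozen=True)
class DistanceState:
    """Pairwise squared Euclidean distances over samples for a gene subset.

    The matrix is symmetric with a zero diagonal; adding gene g increases
    entry (i, j) by (x_ig - x_jg)^2 exactly, which is what
    :func:`extend_distances` exploits.
    """

    sq: np.ndarray
    subset: tuple[int, ...]

    def __post_init__(self) -> None:
        sq = np.asarray(self.sq, dtype=float)
        object.__setattr__(self, "sq", sq)
        object.__setattr__(self, "subset", tuple(int(g) for g in self.subset))
        if sq.ndim != 2 or sq.shape[0] != sq.shape[1]:
            raise ValueError("squared-distance matrix must be square")

    @property
    def n_samples(self) -> int:
        return self.sq.shape[0]


@dataclass(frozen=True)
class WeightedSampleGraph:
    """Symmetric non-negative affinity matrix over samples.

    ``affinity[i, j] > 0`` iff i and j are union-k-NN neighbours, in which
    case the value is exp(-d(i, j)). The diagonal is zero (no self-loops:
    exp(0) = 1 self-weights would inflate every community weight
    identically while adding no class information).
    """

    affinity: np.ndarray
    k: int
    subset: tuple[int, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.affinity, dtype=float)
        object.__setattr__(self, "affinity", a)
        object.__setattr__(self, "subset", tuple(int(g) for g in self.subset))
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("affinity matrix must be square")

    @property
    def n_samples(self) -> int:
        return self.affinity.shape[0]


def squared_distances(
    matrix: ExpressionMatrix, subset: Sequence[int]
) -> DistanceState:
    """Exact pairwise squared Euclidean distances in the given gene subset."""
    subset = tuple(int(g) for g in subset)
    if not subset:
        raise ValueError("gene subset must be non-empty")
    x = matrix.values[:, list(subset)]
    sq = np.zeros((matrix.n_samples, matrix.n_samples))
    for col in x.T:
        diff = col[:, None] - col[None, :]
        sq += diff * diff
    np.fill_diagonal(sq, 0.0)
    return DistanceState(sq, subset)


def extend_distances(
    state: DistanceState, matrix: ExpressionMatrix, gene: int
) -> DistanceState:
    """Squared distances for ``state.subset + (gene,)`` without recomputing.

    Squared L2 distance is additive over genes, so the update is a single
    rank-one-style increment. The input state is left unchanged.
    """
    gene = int(gene)
    if gene in state.subset:
        raise ValueError(f"gene {gene} is already in the subset")
    col = matrix.values[:, gene]
    diff = col[:, None] - col[None, :]
    return DistanceState(state.sq + diff * diff, state.subset + (gene,))


def knn_sets(state: DistanceState, k: int) -> list[tuple[int, ...]]:
    """Each sample's k nearest other samples by squared distance.

    Ties are broken by ascending sample index so results are deterministic
    under input shuffling once sample order is fixed. ``k >= m`` is clamped
    to m-1 with a warning.
    """
    m = state.n_samples
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k >= m:
        warnings.warn(f"k={k} clamped to m-1={m - 1}", stacklevel=2)
        k = m - 1
    sets: list[tuple[int, ...]] = []
    idx = np.arange(m)
    for i in range(m):
        d = state.sq[i].copy()
        d[i] = np.inf  # self excluded
        # lexsort: primary key distance, secondary ascending index
        order = np.lexsort((idx, d))
        sets.append(tuple(int(j) for j in order[:k]))
    return sets


def wsg_from_distances(
    state: DistanceState, k: int, distance_normalize: bool = False
) -> WeightedSampleGraph:
    """Union-k-NN graph with exp(-Euclidean distance) weights.

    ``distance_normalize`` divides distances by sqrt(|subset|) so that
    edge weights keep a comparable scale as the subset grows; the default
    uses raw distances, under which weights shrink with subset size and
    score increments naturally taper.
    """
    m = state.n_samples
    neighbors = knn_sets(state, k)
    k_eff = len(neighbors[0]) if neighbors else 0
    mask = np.zeros((m, m), dtype=bool)
    for i, nbrs in enumerate(neighbors):
        mask[i, list(nbrs)] = True
    mask |= mask.T  # union rule
    d = np.sqrt(state.sq[mask])
    if distance_normalize and state.subset:
        d = d / np.sqrt(len(state.subset))
    a = np.zeros((m, m))
    a[mask] = np.exp(-d)
    np.fill_diagonal(a, 0.0)
    return WeightedSampleGraph(a, k_eff, state.subset)


def build_wsg(
    matrix: ExpressionMatrix,
    subset: Sequence[int],
    k: int,
    distance_normalize: bool = False,
) -> WeightedSampleGraph:
    """Build the weighted sample graph for a gene subset from scratch."""
    return wsg_from_distances(
        squared_distances(matrix, subset), k, distance_normalize
    )


def write_edge_list(graph: WeightedSampleGraph, path: str | Path) -> None:
    """Export the undirected edges as a three-column (i, j, weight) TSV."""
    with Path(path).open("w") as fh:
        fh.write("i\tj\tweight\n")
        ii, jj = np.nonzero(np.triu(graph.affinity, k=1))
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{graph.affinity[i, j]:.17g}\n")
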