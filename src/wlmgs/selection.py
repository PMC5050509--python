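"""Sequential forward greedy gene selection maximizing WLM^s.

The search grows the subset one gene at a time: the first gene is the one
whose single-gene sample graph scores highest, and each later step adds
the candidate whose inclusion yields the highest WLM^s, reusing the
incremental squared-distance state so each candidate costs O(m^2). The
search stops when the best candidate's score increment falls below the
threshold theta (that candidate is *not* added, so the reported subset
never ends on an uninformative gene), when the subset reaches the cap
lambda_max, or when the candidate pool is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data_model import LabeledDataset
from .modularity import wlm_s
from .sample_graph import (
    DistanceState,
    extend_distances,
    squared_distances,
    wsg_from_distances,
)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "select_first_gene",
    "greedy_step",
    "wlmgs_select",
]


@dataclass(frozen=True)
class SelectionConfig:
    """Tuning knobs of the forward search.

    Parameters
    ----------
    k
        Neighbour count of the sample graph; sensible values are small
        (5-11 for datasets with tens of samples).
    lambda_max
        Hard cap on the number of selected genes.
    theta
        Minimum WLM^s increment a candidate must deliver to be accepted
        when ``stop_rule="increment"``. Negative increments always fail
        any non-negative theta.
    candidate_pool
        Optional restriction of the candidate gene indices.
    stop_rule
        ``"increment"`` applies the theta rule; ``"cap-only"`` ignores
        theta and always runs to lambda_max (useful for fixed-length
        accuracy curves).
    """

    k: int = 7
    lambda_max: int = 15
    theta: float = 0.02
    candidate_pool: tuple[int, ...] | None = None
    stop_rule: str = "increment"

    def __post_init__(self) -> None:
        if self.lambda_max < 1:
            raise ValueError("lambda_max must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.stop_rule not in ("increment", "cap-only"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")
        if self.candidate_pool is not None:
            object.__setattr__(
                self, "candidate_pool", tuple(int(g) for g in self.candidate_pool)
            )

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "lambda_max": self.lambda_max,
            "theta": self.theta,
            "candidate_pool": list(self.candidate_pool)
            if self.candidate_pool is not None
            else None,
            "stop_rule": self.stop_rule,
        }


@dataclass(frozen=True)
class SelectionResult:
    """Selected genes in order with the WLM^s trajectory.

    ``increments[0]`` is the first gene's score itself; later entries are
    first differences of ``scores``. ``stopped_by`` records which rule
    terminated the search.
    """

    genes: tuple[int, ...]
    scores: tuple[float, ...]
    stopped_by: str
    config: SelectionConfig = field(repr=False, default=SelectionConfig())

    @property
    def increments(self) -> tuple[float, ...]:
        return tuple(
            s - p for s, p in zip(self.scores, (0.0,) + self.scores[:-1])
        )

    def gene_ids(self, dataset: LabeledDataset) -> tuple[str, ...]:
        return tuple(dataset.matrix.gene_ids[g] for g in self.genes)

    def to_dict(self, dataset: LabeledDataset | None = None) -> dict:
        out = {
            "genes": list(self.genes),
            "scores": list(self.scores),
            "increments": list(self.increments),
            "stopped_by": self.stopped_by,
            "config": self.config.to_dict(),
        }
        if dataset is not None:
            out["gene_ids"] = list(self.gene_ids(dataset))
        return out


def _score(state: DistanceState, labels: Sequence[str], k: int) -> float:
    return wlm_s(wsg_from_distances(state, k), labels).value


def _candidates(dataset: LabeledDataset, config: SelectionConfig) -> list[int]:
    if config.candidate_pool is not None:
        pool = sorted(set(config.candidate_pool))
        bad = [g for g in pool if not 0 <= g < dataset.matrix.n_genes]
        if bad:
            raise ValueError(f"candidate pool indices out of range: {bad}")
        return pool
    return list(range(dataset.matrix.n_genes))


def select_first_gene(dataset: LabeledDataset, config: SelectionConfig) -> int:
    """Argmax of WLM^s over single-gene subsets; ties -> smallest index."""
    gene, _ = _best_first(dataset, config)
    return gene


def _best_first(
    dataset: LabeledDataset, config: SelectionConfig
) -> tuple[int, float]:
    pool = _candidates(dataset, config)
    if not pool:
        raise ValueError("candidate pool is empty")
    best_gene, best_score = -1, -np.inf
    for g in pool:  # ascending order; strict '>' keeps the smallest index
        score = _score(squared_distances(dataset.matrix, (g,)), dataset.labels, config.k)
        if score > best_score:
            best_gene, best_score = g, score
    return best_gene, best_score


def greedy_step(
    dataset: LabeledDataset,
    current: Sequence[int],
    state: DistanceState,
    config: SelectionConfig,
) -> tuple[int, float]:
    """Best single-gene extension of ``current`` and its WLM^s.

    Evaluates every remaining candidate with the incremental distance
    update; ties are broken towards the smallest gene index. Raises
    ``LookupError`` when no candidate remains.
    """
    current = tuple(int(g) for g in current)
    if not current:
        raise ValueError("current subset must be non-empty")
    remaining = [g for g in _candidates(dataset, config) if g not in set(current)]
    if not remaining:
        raise LookupError("candidate pool exhausted")
    best_gene, best_score = -1, -np.inf
    for g in remaining:
        score = _score(extend_distances(state, dataset.matrix, g), dataset.labels, config.k)
        if score > best_score:
            best_gene, best_score = g, score
    return best_gene, best_score


def wlmgs_select(
    dataset: LabeledDataset, config: SelectionConfig = SelectionConfig()
) -> SelectionResult:
    """Run the full forward search on an already-normalized dataset.

    Notes
    -----
    The caller is responsible for normalization (the cross-validation
    harness z-scores on training folds only); this function scores the
    matrix as given.
    """
    first, first_score = _best_first(dataset, config)
    genes = [first]
    scores = [first_score]
    state = squared_distances(dataset.matrix, (first,))

    use_theta = config.stop_rule == "increment"
    while True:
        if len(genes) >= config.lambda_max:
            return SelectionResult(tuple(genes), tuple(scores), "lambda", config)
        try:
            gene, score = greedy_step(dataset, genes, state, config)
        except LookupError:
            return SelectionResult(tuple(genes), tuple(scores), "pool-exhausted", config)
        if use_theta and score - scores[-1] < config.theta:
            # reject the sub-threshold candidate: stop *before* adding
            return SelectionResult(tuple(genes), tuple(scores), "theta", config)
        genes.append(gene)
        scores.append(score)
        state = extend_distances(state, dataset.matrix, gene)
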