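"""Cross-validated evaluation of selected gene subsets.

Per fold: z-score on the training samples only, run the forward search on
the training portion, then classify the held-out samples (transformed
with the *training* statistics) on the selected genes with 1NN and an
RBF-kernel SVM (C=100). Across folds, genes are ranked by how often they
were selected ("frequency consensus"). The k-means within-class objective
is exposed for the score-vs-clustering sanity check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .data_model import ExpressionMatrix, GeneScaler, LabeledDataset
from .selection import SelectionConfig, SelectionResult, wlmgs_select

__all__ = [
    "FoldResult",
    "CVReport",
    "stratified_folds",
    "one_nn_classify",
    "svm_classify",
    "cross_validated_selection",
    "accuracy_curve",
    "kmeans_objective",
]

#: classifier name -> (train X, train y, test X) -> predicted labels
CLASSIFIERS: dict[str, Callable] = {}


@dataclass(frozen=True)
class FoldResult:
    """One fold's selected genes and held-out accuracies."""

    test_indices: tuple[int, ...]
    selection: SelectionResult
    accuracy: dict[str, float]


@dataclass(frozen=True)
class CVReport:
    """Cross-validation summary: per-fold subsets, consensus and accuracy.

    ``consensus_genes`` ranks genes by selection frequency across folds
    (ties by mean selection rank, then index); ``consensus_subset`` keeps
    the top genes, as many as the most common fold-subset size.
    """

    folds: tuple[FoldResult, ...]
    frequencies: dict[int, int]
    consensus_genes: tuple[int, ...]
    consensus_subset: tuple[int, ...]
    mean_accuracy: dict[str, float]
    mean_subset_size: float
    config: dict = field(repr=False, default_factory=dict)

    def to_dict(self, dataset: LabeledDataset | None = None) -> dict:
        ids = (lambda g: dataset.matrix.gene_ids[g]) if dataset else (lambda g: g)
        return {
            "folds": [
                {
                    "test_indices": list(f.test_indices),
                    "selection": f.selection.to_dict(dataset),
                    "accuracy": dict(f.accuracy),
                }
                for f in self.folds
            ],
            "frequencies": {str(ids(g)): c for g, c in self.frequencies.items()},
            "consensus_genes": [ids(g) for g in self.consensus_genes],
            "consensus_subset": [ids(g) for g in self.consensus_subset],
            "mean_accuracy": dict(self.mean_accuracy),
            "mean_subset_size": self.mean_subset_size,
            "config": dict(self.config),
        }


def stratified_folds(
    labels: Sequence[str], n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled, class-stratified train/test index splits.

    Falls back to plain shuffled folds (with a warning) when some class
    has fewer members than ``n_folds``; such tiny classes make stratified
    splitting impossible.
    """
    y = np.asarray([str(x) for x in labels], dtype=object)
    m = y.shape[0]
    if n_folds > m:
        raise ValueError(f"n_folds={n_folds} exceeds {m} samples")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        warnings.warn(
            f"smallest class has {counts.min()} < {n_folds} samples; "
            "using unstratified shuffled folds",
            stacklevel=2,
        )
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in splitter.split(y)]
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros((m, 1)), y)]


def one_nn_classify(
    train_x: np.ndarray, train_y: Sequence[str], test_x: np.ndarray
) -> np.ndarray:
    """Nearest-neighbour labels under Euclidean distance.

    Distance ties resolve to the smallest training index (argmin returns
    the first minimum), keeping predictions deterministic.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    if train_x.shape[0] == 0:
        raise ValueError("empty training set")
    d = cdist(test_x, train_x, metric="sqeuclidean")
    train_y = np.asarray([str(v) for v in train_y], dtype=object)
    return train_y[np.argmin(d, axis=1)]


def svm_classify(
    train_x: np.ndarray,
    train_y: Sequence[str],
    test_x: np.ndarray,
    C: float = 100.0,
) -> np.ndarray:
    """RBF-kernel soft-margin SVM predictions at the given C.

    The kernel bandwidth uses the 1/(n_features * variance) heuristic and
    multiclass problems are handled one-vs-one. A degenerate single-class
    training fold predicts that class for everything, with a warning.
    """
    train_y = np.asarray([str(v) for v in train_y], dtype=object)
    test_x = np.atleast_2d(np.asarray(test_x, dtype=float))
    if len(set(train_y)) == 1:
        warnings.warn("single-class training fold; predicting that class",
                      stacklevel=2)
        return np.full(test_x.shape[0], train_y[0], dtype=object)
    clf = SVC(C=C, kernel="rbf", gamma="scale")
    clf.fit(np.atleast_2d(np.asarray(train_x, dtype=float)), train_y)
    return clf.predict(test_x).astype(object)


CLASSIFIERS["1nn"] = one_nn_classify
CLASSIFIERS["svm"] = svm_classify


def _rank_consensus(
    selections: list[SelectionResult],
) -> tuple[dict[int, int], tuple[int, ...], tuple[int, ...]]:
    freq: dict[int, int] = {}
    ranks: dict[int, list[int]] = {}
    for sel in selections:
        for rank, g in enumerate(sel.genes):
            freq[g] = freq.get(g, 0) + 1
            ranks.setdefault(g, []).append(rank)
    ordered = sorted(
        freq, key=lambda g: (-freq[g], float(np.mean(ranks[g])), g)
    )
    sizes = [len(sel.genes) for sel in selections]
    vals, counts = np.unique(sizes, return_counts=True)
    mode_size = int(vals[np.argmax(counts)])  # ties -> smallest size
    return freq, tuple(ordered), tuple(ordered[:mode_size])


def cross_validated_selection(
    dataset: LabeledDataset,
    config: SelectionConfig = SelectionConfig(),
    n_folds: int = 10,
    repeats: int = 1,
    seed: int = 0,
    classifiers: Sequence[str] = ("1nn", "svm"),
    global_normalize: bool = False,
) -> CVReport:
    """Select genes per training fold and score the held-out samples.

    Normalization statistics come from the training fold only (held-out
    samples are transformed with training means/SDs) unless
    ``global_normalize`` forces a single whole-dataset z-scoring.
    Repeats rerun the whole fold split with shifted seeds; fold entries
    accumulate and the mean accuracy is the grand mean.
    """
    unknown = [c for c in classifiers if c not in CLASSIFIERS]
    if unknown:
        raise ValueError(f"unknown classifiers {unknown}; have {sorted(CLASSIFIERS)}")
    y = dataset.label_array()
    folds: list[FoldResult] = []
    if global_normalize:
        pre = GeneScaler().fit_transform(dataset.matrix)
    for rep in range(repeats):
        for train_idx, test_idx in stratified_folds(
            dataset.labels, n_folds, seed + rep
        ):
            if global_normalize:
                train_m = pre.subset_samples(train_idx)
                test_m = pre.subset_samples(test_idx)
            else:
                scaler = GeneScaler().fit(dataset.matrix.subset_samples(train_idx))
                train_m = scaler.transform(dataset.matrix.subset_samples(train_idx))
                test_m = scaler.transform(dataset.matrix.subset_samples(test_idx))
            train_ds = LabeledDataset(train_m, tuple(y[train_idx]))
            sel = wlmgs_select(train_ds, config)
            genes = list(sel.genes)
            acc: dict[str, float] = {}
            for name in classifiers:
                pred = CLASSIFIERS[name](
                    train_m.values[:, genes], y[train_idx], test_m.values[:, genes]
                )
                acc[name] = float(np.mean(pred == y[test_idx]))
            folds.append(FoldResult(tuple(int(i) for i in test_idx), sel, acc))
    freq, ordered, consensus = _rank_consensus([f.selection for f in folds])
    mean_acc = {
        name: float(np.mean([f.accuracy[name] for f in folds]))
        for name in classifiers
    }
    return CVReport(
        folds=tuple(folds),
        frequencies=freq,
        consensus_genes=ordered,
        consensus_subset=consensus,
        mean_accuracy=mean_acc,
        mean_subset_size=float(np.mean([len(f.selection.genes) for f in folds])),
        config={
            "n_folds": n_folds,
            "repeats": repeats,
            "seed": seed,
            "classifiers": list(classifiers),
            "global_normalize": global_normalize,
            "selection": config.to_dict(),
        },
    )


def accuracy_curve(
    dataset: LabeledDataset,
    ranked_genes: Sequence[int],
    classifier: str = "1nn",
    max_genes: int | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> list[float]:
    """Cross-validated accuracy of the top-g gene prefixes, g = 1..max.

    The gene ranking is taken as fixed (e.g. a consensus ranking); only
    the classifier is re-fitted per fold, so this traces how accuracy
    responds to subset size.
    """
    ranked = [int(g) for g in ranked_genes]
    if not ranked:
        raise ValueError("ranked gene list must be non-empty")
    if max_genes is None:
        max_genes = len(ranked)
    y = dataset.label_array()
    splits = stratified_folds(dataset.labels, n_folds, seed)
    curve: list[float] = []
    for g in range(1, min(max_genes, len(ranked)) + 1):
        genes = ranked[:g]
        accs = []
        for train_idx, test_idx in splits:
            scaler = GeneScaler().fit(dataset.matrix.subset_samples(train_idx))
            train_m = scaler.transform(dataset.matrix.subset_samples(train_idx))
            test_m = scaler.transform(dataset.matrix.subset_samples(test_idx))
            pred = CLASSIFIERS[classifier](
                train_m.values[:, genes], y[train_idx], test_m.values[:, genes]
            )
            accs.append(float(np.mean(pred == y[test_idx])))
        curve.append(float(np.mean(accs)))
    return curve


def kmeans_objective(
    matrix: ExpressionMatrix | np.ndarray,
    labels: Sequence[str],
    squared: bool = True,
) -> float:
    """Within-class scatter J = sum_i ||x_i - mu_c(i)||^2.

    Cluster centres are the class-conditional means of the given labels
    (no iteration — communities are fixed). ``squared=False`` switches to
    plain Euclidean distances for sensitivity checks.
    """
    x = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, dtype=float)
    x = np.atleast_2d(x)
    y = np.asarray([str(v) for v in labels], dtype=object)
    if y.shape[0] != x.shape[0]:
        raise ValueError("label/matrix size mismatch")
    total = 0.0
    for cls in np.unique(y):
        pts = x[y == cls]
        sq = ((pts - pts.mean(axis=0)) ** 2).sum(axis=1)
        total += float(sq.sum() if squared else np.sqrt(sq).sum())
    return total
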