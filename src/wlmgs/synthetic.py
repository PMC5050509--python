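"""Synthetic class-structured expression data with known ground truth.

The generator emulates the regime the selection method targets: tens of
samples, 10^2-10^4 genes, 2-5 classes. Informative genes are Gaussian
with class-dependent means (class centroids sit on a simplex so no class
pair is favoured), noise genes are class-independent N(0, 1), redundant
genes are jittered copies of informative ones, and optional outlier
samples are overdispersed rows that keep their true labels. It does not
model intensity-dependent variance or batch effects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .data_model import ExpressionMatrix, LabeledDataset
from .sample_graph import WeightedSampleGraph, build_wsg

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "fixture_graph"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic labelled dataset.

    ``effect_size`` is the Euclidean separation between class centroids in
    within-class-SD units, spread across the informative genes; 0 makes
    "informative" genes statistically indistinguishable from noise.
    ``samples_per_class`` may be unequal to model class imbalance.
    """

    n_classes: int = 2
    samples_per_class: tuple[int, ...] = (30, 30)
    n_informative: int = 5
    n_noise: int = 95
    effect_size: float = 2.0
    n_redundant: int = 0
    redundant_jitter_sd: float = 0.1
    n_outlier_samples: int = 0
    outlier_sd: float = 5.0
    within_class_clusters: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples_per_class", tuple(int(x) for x in self.samples_per_class)
        )
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        if any(x < 1 for x in self.samples_per_class):
            raise ValueError("every class needs at least 1 sample")
        if min(self.n_informative, self.n_noise, self.n_redundant) < 0:
            raise ValueError("gene counts must be >= 0")
        if self.n_informative + self.n_noise + self.n_redundant < 1:
            raise ValueError("need at least one gene")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant genes require informative genes to copy")
        if self.n_outlier_samples > sum(self.samples_per_class):
            raise ValueError("more outliers than samples")


@dataclass(frozen=True)
class GroundTruth:
    """Which gene columns are informative, redundant copies, or pure noise."""

    informative: tuple[int, ...]
    redundant: tuple[int, ...]
    noise: tuple[int, ...]


def _simplex(c: int) -> np.ndarray:
    """c equidistant points in R^(c-1), unit pairwise distance, centred."""
    eye = np.eye(c)
    pts = (eye - eye.mean(axis=0)) / np.sqrt(2.0)  # pairwise distance 1
    # drop the redundant dimension
    q, _ = np.linalg.qr(pts.T, mode="reduced")
    return pts @ q[:, : c - 1]


def _class_means(spec: SyntheticSpec) -> np.ndarray:
    """(n_classes x n_informative) means, effect_size separation per gene.

    Simplex coordinates are tiled cyclically over the informative genes
    and scaled by effect_size, so each informative gene carries a
    class-mean shift of effect_size within-class SDs (for two classes,
    means at +/- effect_size/2 on every informative gene).
    """
    if spec.n_informative == 0:
        return np.zeros((spec.n_classes, 0))
    base = _simplex(spec.n_classes)  # (C, C-1), unit pairwise distance
    means = np.zeros((spec.n_classes, spec.n_informative))
    dim = base.shape[1]
    for g in range(spec.n_informative):
        means[:, g] = spec.effect_size * base[:, g % dim]
    return means


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Draw one dataset and its ground-truth gene partition.

    Gene columns are ordered informative, redundant, noise; the
    :class:`GroundTruth` records the index sets so tests never depend on
    that ordering convention.
    """
    rng = np.random.default_rng(spec.seed)
    m = sum(spec.samples_per_class)
    labels = np.repeat(
        [f"class{i}" for i in range(spec.n_classes)], spec.samples_per_class
    )

    means = _class_means(spec)  # (C, n_informative)
    per_sample_mean = means[np.repeat(np.arange(spec.n_classes), spec.samples_per_class)]
    if spec.within_class_clusters and spec.within_class_clusters > 1 and spec.n_informative:
        # sub-cluster shifts within each class, zero-mean so the class
        # centroid is preserved on average
        shifts = rng.normal(
            0.0,
            spec.effect_size / 2.0,
            size=(spec.n_classes, spec.within_class_clusters, spec.n_informative),
        )
        shifts -= shifts.mean(axis=1, keepdims=True)
        start = 0
        for c, n_c in enumerate(spec.samples_per_class):
            assign = rng.integers(0, spec.within_class_clusters, size=n_c)
            per_sample_mean[start : start + n_c] += shifts[c, assign]
            start += n_c

    informative = per_sample_mean + rng.normal(0.0, 1.0, size=(m, spec.n_informative))
    noise = rng.normal(0.0, 1.0, size=(m, spec.n_noise))
    if spec.n_redundant:
        src = rng.integers(0, spec.n_informative, size=spec.n_redundant)
        redundant = informative[:, src] + rng.normal(
            0.0, spec.redundant_jitter_sd, size=(m, spec.n_redundant)
        )
    else:
        redundant = np.zeros((m, 0))

    values = np.concatenate([informative, redundant, noise], axis=1)
    if spec.n_outlier_samples:
        rows = rng.choice(m, size=spec.n_outlier_samples, replace=False)
        values[rows] = rng.normal(0.0, spec.outlier_sd, size=(len(rows), values.shape[1]))

    n_inf, n_red = spec.n_informative, spec.n_redundant
    truth = GroundTruth(
        informative=tuple(range(n_inf)),
        redundant=tuple(range(n_inf, n_inf + n_red)),
        noise=tuple(range(n_inf + n_red, values.shape[1])),
    )
    matrix = ExpressionMatrix(
        values,
        tuple(f"s{i}" for i in range(m)),
        tuple(f"g{j}" for j in range(values.shape[1])),
    )
    return LabeledDataset(matrix, tuple(labels)), truth


def _graph(a: np.ndarray, k: int) -> WeightedSampleGraph:
    a = np.asarray(a, dtype=float)
    return WeightedSampleGraph((a + a.T) / 2.0 if not np.allclose(a, a.T) else a, k, ())


_FIXTURES = ("isolated-pairs", "path-4", "two-triangles", "random(m, C, seed)")


def fixture_graph(name: str) -> tuple[WeightedSampleGraph, tuple[str, ...]]:
    """Small named labelled graphs used as worked modularity examples.

    * ``isolated-pairs`` — samples at 0, 1, 10, 11 on one gene, k=1: two
      disjoint same-class edges of weight e^-1; WLM^s = 2.
    * ``path-4`` — samples at 0, 2, 3, 5, k=1: a path with edge weights
      e^-2, e^-1, e^-2 and a class boundary across the middle edge.
    * ``two-triangles`` — two unit-weight 3-cliques, one class each.
    * ``random(m, C, seed)`` — Gaussian points, union-3-NN graph, cyclic
      labels; reproducible from seed.
    """
    name = name.strip()
    if name == "isolated-pairs":
        points, labels, k = [0.0, 1.0, 10.0, 11.0], ("A", "A", "B", "B"), 1
    elif name == "path-4":
        points, labels, k = [0.0, 2.0, 3.0, 5.0], ("A", "A", "B", "B"), 1
    elif name == "two-triangles":
        a = np.zeros((6, 6))
        for block in (slice(0, 3), slice(3, 6)):
            a[block, block] = 1.0
        np.fill_diagonal(a, 0.0)
        return _graph(a, 2), ("A",) * 3 + ("B",) * 3
    else:
        m = re.fullmatch(r"random\(\s*(\d+)\s*,\s*(\d+)\s*,\s*(\d+)\s*\)", name)
        if not m:
            raise ValueError(f"unknown fixture {name!r}; valid: {_FIXTURES}")
        n, c, seed = map(int, m.groups())
        if n < c or c < 2:
            raise ValueError("random fixture needs m >= C >= 2")
        rng = np.random.default_rng(seed)
        mat = ExpressionMatrix(
            rng.normal(size=(n, 3)),
            tuple(f"s{i}" for i in range(n)),
            ("g0", "g1", "g2"),
        )
        labels = tuple(f"c{i % c}" for i in range(n))
        return build_wsg(mat, (0, 1, 2), min(3, n - 1)), labels
    mat = ExpressionMatrix(
        np.asarray(points)[:, None],
        tuple(f"s{i}" for i in range(len(points))),
        ("g0",),
    )
    return build_wsg(mat, (0,), k), labels
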