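"""Expression-data containers, delimited-text I/O and per-gene z-scoring.

The canonical in-memory orientation is samples x genes: every distance in
this package is a distance between samples, so samples-major access
dominates. Files may store either orientation; readers reorient on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "LabeledDataset",
    "GeneScaler",
    "read_expression",
    "write_expression",
    "read_labels",
    "attach_labels",
    "zscore_normalize",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """A samples x genes matrix of expression values with identifiers.

    Parameters
    ----------
    values
        Real matrix, one row per sample, one column per gene. Any
        expression units; selection always z-scores first.
    sample_ids, gene_ids
        Unique string identifiers for rows and columns respectively.
    """

    values: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "gene_ids", tuple(map(str, self.gene_ids)))
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={values.ndim}")
        if values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {self.sample_ids[i]!r}, "
                f"gene {self.gene_ids[j]!r}"
            )
        for name, ids in (("sample", self.sample_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dups = sorted({x for x in ids if x in seen or seen.add(x)})
                raise ValueError(f"duplicate {name} identifiers: {dups}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Sequence[int]) -> "ExpressionMatrix":
        """New matrix restricted to the given gene column indices, in order."""
        idx = list(genes)
        return ExpressionMatrix(
            self.values[:, idx],
            self.sample_ids,
            tuple(self.gene_ids[g] for g in idx),
        )

    def subset_samples(self, samples: Sequence[int]) -> "ExpressionMatrix":
        idx = list(samples)
        return ExpressionMatrix(
            self.values[idx, :],
            tuple(self.sample_ids[i] for i in idx),
            self.gene_ids,
        )


@dataclass(frozen=True)
class LabeledDataset:
    """Expression matrix plus a per-sample class assignment.

    ``labels`` is aligned with ``matrix.sample_ids``. At least two classes
    are required and every class must be non-empty.
    """

    matrix: ExpressionMatrix
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(map(str, self.labels)))
        if len(self.labels) != self.matrix.n_samples:
            raise ValueError(
                f"{len(self.labels)} labels for {self.matrix.n_samples} samples"
            )
        if len(self.classes) < 2:
            raise ValueError(
                f"need at least 2 classes, got {sorted(set(self.labels))}"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels)))

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def label_array(self) -> np.ndarray:
        return np.asarray(self.labels, dtype=object)

    def subset_samples(self, samples: Sequence[int]) -> "LabeledDataset":
        idx = list(samples)
        return LabeledDataset(
            self.matrix.subset_samples(idx),
            tuple(self.labels[i] for i in idx),
        )


def _sniff_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression table into samples x genes orientation.

    Parameters
    ----------
    path
        TSV or CSV file with one header row and one identifier column.
    orientation
        ``"samples-in-rows"`` (header = gene ids) or ``"genes-in-rows"``
        (header = sample ids; the matrix is transposed on load).
    sep
        Field separator; inferred from the extension when omitted
        (``.csv`` -> comma, else tab).
    """
    path = Path(path)
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sniff_sep(path, sep), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    try:
        body = df.astype(float)
    except ValueError:
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[np.flatnonzero(bad.to_numpy())[0]]
                raise ValueError(
                    f"non-numeric cell at row {row!r}, column {col!r} in {path}"
                ) from None
        raise
    if body.isna().any().any():
        j = body.columns[body.isna().any().to_numpy()][0]
        i = body.index[body[j].isna().to_numpy()][0]
        raise ValueError(f"missing value at row {i!r}, column {j!r} in {path}")
    if orientation == "genes-in-rows":
        body = body.T
    return ExpressionMatrix(
        body.to_numpy(dtype=float),
        tuple(map(str, body.index)),
        tuple(map(str, body.columns)),
    )


def write_expression(
    matrix: ExpressionMatrix,
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
) -> None:
    """Write the matrix as delimited text; inverse of :func:`read_expression`.

    Values are written with :func:`repr` precision so that a read/write
    cycle round-trips exactly.
    """
    path = Path(path)
    df = pd.DataFrame(
        matrix.values, index=list(matrix.sample_ids), columns=list(matrix.gene_ids)
    )
    if orientation == "genes-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.to_csv(path, sep=_sniff_sep(path, sep), float_format="%.17g")


def read_labels(
    path: str | Path, sep: str | None = None, header: bool = False
) -> dict[str, str]:
    """Read a two-column sample_id -> class label file.

    ``header`` must be set explicitly when the file carries one; labels are
    arbitrary strings so header rows cannot be reliably auto-detected.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sniff_sep(path, sep),
        header=0 if header else None,
        dtype=str,
    )
    if df.shape[1] < 2:
        raise ValueError(f"label file {path} needs two columns, got {df.shape[1]}")
    pairs = df.iloc[:, :2].dropna()
    mapping: dict[str, str] = {}
    for sid, lab in pairs.itertuples(index=False):
        sid, lab = str(sid), str(lab)
        if sid in mapping and mapping[sid] != lab:
            raise ValueError(f"conflicting labels for sample {sid!r} in {path}")
        mapping[sid] = lab
    return mapping


def attach_labels(
    matrix: ExpressionMatrix, labels: dict[str, str]
) -> LabeledDataset:
    """Align a sample -> label mapping with a matrix's sample order.

    Samples present in the matrix but missing from ``labels`` are an error;
    labels for unknown samples are ignored with a warning.
    """
    missing = [s for s in matrix.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"samples missing from label file: {missing}")
    unknown = sorted(set(labels) - set(matrix.sample_ids))
    if unknown:
        warnings.warn(
            f"ignoring labels for unknown samples: {unknown}", stacklevel=2
        )
    return LabeledDataset(matrix, tuple(labels[s] for s in matrix.sample_ids))


@dataclass
class GeneScaler:
    """Per-gene z-scoring fitted on one matrix and applicable to another.

    Centering and scaling statistics come from the matrix passed to
    :meth:`fit` only, so held-out samples can be transformed with training
    statistics and never leak into them. The standard deviation uses the
    sample (m-1) denominator. Genes that are constant in the fitted matrix
    are mapped to all-zero (they carry no distance information) and listed
    in :attr:`constant_genes`.
    """

    means_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    sds_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    constant_genes: tuple[str, ...] = ()

    def fit(self, matrix: ExpressionMatrix) -> "GeneScaler":
        if matrix.n_samples < 2:
            raise ValueError("z-scoring needs at least 2 samples")
        self.means_ = matrix.values.mean(axis=0)
        self.sds_ = matrix.values.std(axis=0, ddof=1)
        const = self.sds_ == 0.0
        self.constant_genes = tuple(
            g for g, c in zip(matrix.gene_ids, const) if c
        )
        return self

    def transform(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        if self.means_ is None:
            raise RuntimeError("GeneScaler is not fitted")
        if matrix.n_genes != self.means_.shape[0]:
            raise ValueError("gene count differs from the fitted matrix")
        safe = np.where(self.sds_ == 0.0, 1.0, self.sds_)
        out = (matrix.values - self.means_) / safe
        out[:, self.sds_ == 0.0] = 0.0
        return ExpressionMatrix(out, matrix.sample_ids, matrix.gene_ids)

    def fit_transform(self, matrix: ExpressionMatrix) -> ExpressionMatrix:
        return self.fit(matrix).transform(matrix)


def zscore_normalize(
    matrix: ExpressionMatrix,
) -> tuple[ExpressionMatrix, tuple[str, ...]]:
    """Z-score every gene to mean 0 and sample SD 1 (m-1 denominator).

    Returns the normalized matrix and the ids of constant genes, which are
    mapped to all-zero columns rather than erroring.
    """
    scaler = GeneScaler().fit(matrix)
    return scaler.transform(matrix), scaler.constant_genes
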