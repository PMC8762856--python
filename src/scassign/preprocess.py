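"""Expression-matrix ingestion, normalization and feature extraction.

The container is a thin cells x genes sparse wrapper.  Every operation
keeps the full matrix sparse; the only dense object ever produced is the
small cells x features submatrix a classifier actually consumes.  A
module-level monitor records the widest submatrix densified so far, so
tests (and worried users) can verify that classifying a large dataset
never materializes a dense cells x genes array.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import (
    DegenerateCellError,
    EmptyOverlapError,
    FormatError,
    ShapeError,
    ValidityError,
)

__all__ = [
    "ExpressionMatrix",
    "FeatureMatrix",
    "read_expression",
    "normalize_counts",
    "extract_features",
    "standardize",
    "reset_densify_peak",
    "get_densify_peak",
]

# widest cells x features block densified since the last reset
_DENSIFY_PEAK_COLUMNS = 0


def reset_densify_peak() -> None:
    global _DENSIFY_PEAK_COLUMNS
    _DENSIFY_PEAK_COLUMNS = 0


def get_densify_peak() -> int:
    """Peak number of columns densified at once since the last reset."""
    return _DENSIFY_PEAK_COLUMNS


def _record_densify(n_columns: int) -> None:
    global _DENSIFY_PEAK_COLUMNS
    _DENSIFY_PEAK_COLUMNS = max(_DENSIFY_PEAK_COLUMNS, n_columns)


@dataclass
class ExpressionMatrix:
    """Cells x genes sparse nonnegative expression matrix."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    is_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        n_cells, n_genes = self.values.shape
        if len(self.cell_ids) != n_cells:
            raise ShapeError(f"{len(self.cell_ids)} cell_ids for {n_cells} matrix rows")
        if len(self.gene_ids) != n_genes:
            raise ShapeError(f"{len(self.gene_ids)} gene_ids for {n_genes} matrix columns")
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("cell identifiers are not unique")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("gene identifiers are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidityError("expression matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask_or_index) -> "ExpressionMatrix":
        idx = np.asarray(mask_or_index)
        return ExpressionMatrix(
            self.values[idx], self.cell_ids[idx], self.gene_ids, self.is_normalized
        )


@dataclass
class FeatureMatrix:
    """Dense cells x features block in a classifier's feature order.

    Features absent from the source matrix appear as zero columns and
    are listed in ``missing_features``.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    feature_names: tuple[str, ...]
    missing_features: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_names = tuple(self.feature_names)
        self.missing_features = tuple(self.missing_features)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ShapeError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.feature_names)} feature names"
            )


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _find_member(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FormatError(f"{directory} does not contain {stem}[.gz]")


def _read_tsv_column(path: Path, prefer_second: bool) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise FormatError(f"{path} is empty")
    col = 1 if (prefer_second and len(rows[0]) > 1) else 0
    return [r[col] for r in rows]


def _read_mtx_dir(directory: Path) -> tuple[sp.csr_matrix, list[str], list[str]]:
    mtx = _find_member(directory, "matrix.mtx")
    feats = _read_tsv_column(_find_member(directory, "features.tsv"), prefer_second=True)
    barcodes = _read_tsv_column(_find_member(directory, "barcodes.tsv"), prefer_second=False)
    with _open_maybe_gzip(mtx) as fh:
        try:
            m = scipy.io.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"cannot parse {mtx}: {exc}") from exc
    m = sp.csr_matrix(m)
    return m, feats, barcodes


def read_expression(path, format: str, orientation: str = "genes_by_cells") -> ExpressionMatrix:
    """Read a count matrix from a 10x-style MTX directory or a CSV file.

    ``orientation`` describes the on-disk layout; the returned matrix is
    always cells x genes.  The result is flagged un-normalized; callers
    holding pre-normalized data set ``is_normalized`` themselves.
    """
    path = Path(path)
    if orientation not in ("genes_by_cells", "cells_by_genes"):
        raise ValidityError(f"unknown orientation {orientation!r}")
    if format == "mtx_dir":
        m, features, barcodes = _read_mtx_dir(path)
        if orientation == "genes_by_cells":
            rows, cols = features, barcodes
        else:
            rows, cols = barcodes, features
        if m.shape[0] != len(rows):
            raise FormatError(
                f"matrix has {m.shape[0]} rows but {len(rows)} row identifiers"
            )
        if m.shape[1] != len(cols):
            raise FormatError(
                f"matrix has {m.shape[1]} columns but {len(cols)} column identifiers"
            )
        if orientation == "genes_by_cells":
            m = sp.csr_matrix(m.T)
            cell_ids, gene_ids = barcodes, features
        else:
            cell_ids, gene_ids = barcodes, features
    elif format == "csv":
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
        df = pd.read_csv(path, index_col=0, sep=sep)
        if orientation == "genes_by_cells":
            df = df.T
        m = sp.csr_matrix(df.to_numpy(dtype=np.float64))
        cell_ids, gene_ids = list(df.index.astype(str)), list(df.columns.astype(str))
    else:
        raise ValidityError(f"unknown format {format!r}; expected 'mtx_dir' or 'csv'")
    return ExpressionMatrix(m, np.array(cell_ids, dtype=object),
                            np.array(gene_ids, dtype=object), is_normalized=False)


def normalize_counts(m: ExpressionMatrix, scale_total: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization: scale each cell to ``scale_total`` counts, then log1p.

    Zeros stay zeros, so sparsity is preserved exactly.
    """
    if m.is_normalized:
        raise ValidityError("matrix is already normalized")
    if scale_total <= 0:
        raise ValidityError("scale_total must be positive")
    totals = np.asarray(m.values.sum(axis=1)).ravel()
    zero = totals == 0
    if zero.any():
        offenders = list(m.cell_ids[zero][:10])
        raise DegenerateCellError(
            f"{zero.sum()} cell(s) have zero total counts, e.g. {offenders}"
        )
    out = sp.csr_matrix(m.values, copy=True).astype(np.float64)
    scale = scale_total / totals
    # scale each row in place on the sparse data array
    row_rep = np.repeat(scale, np.diff(out.indptr))
    out.data *= row_rep
    np.log1p(out.data, out=out.data)
    return ExpressionMatrix(out, m.cell_ids, m.gene_ids, is_normalized=True)


def extract_features(m: ExpressionMatrix, features: Sequence[str]) -> FeatureMatrix:
    """Pull the requested genes, in order, as a dense cells x features block.

    Genes absent from the matrix become zero columns (and a warning is
    emitted naming them); if no requested gene is present the overlap is
    empty and an error is raised instead.
    """
    features = list(features)
    if not m.is_normalized:
        raise ValidityError("extract_features expects a normalized matrix")
    col_of = {g: j for j, g in enumerate(m.gene_ids)}
    present = [f for f in features if f in col_of]
    missing = [f for f in features if f not in col_of]
    if not present:
        raise EmptyOverlapError(
            f"none of the {len(features)} requested features are in the matrix"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} requested feature(s) absent from the matrix, "
            f"zero-filled: {missing}",
            stacklevel=2,
        )
    _record_densify(len(features))
    out = np.zeros((m.n_cells, len(features)), dtype=np.float64)
    src_cols = [col_of[f] for f in present]
    dst_cols = [j for j, f in enumerate(features) if f in col_of]
    out[:, dst_cols] = m.values[:, src_cols].toarray()
    return FeatureMatrix(out, m.cell_ids, tuple(features), tuple(missing))


def standardize(fm: FeatureMatrix, means, sds) -> FeatureMatrix:
    """Apply per-column z-scoring with training-time constants."""
    means = np.asarray(means, dtype=np.float64)
    sds = np.asarray(sds, dtype=np.float64)
    k = len(fm.feature_names)
    if means.shape != (k,) or sds.shape != (k,):
        raise ShapeError(
            f"means/sds shapes {means.shape}/{sds.shape} do not match {k} features"
        )
    if np.any(sds <= 0):
        raise ShapeError("all sds must be strictly positive")
    z = (fm.values - means) / sds
    return FeatureMatrix(z, fm.cell_ids, fm.feature_names, fm.missing_features)
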