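"""Shared fixtures: hand-constructible classifiers whose probabilities
can be dialed exactly, and small expression matrices."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from scassign import CellClassifier, ClassifierDatabase, ExpressionMatrix, LinearBinaryModel, add_classifier

# Stub classifiers read a single dedicated gene: with w=1, b=0, mean=0,
# sd=1, A=-1, B=OFFSET, the probability of a cell is
# sigmoid(x - OFFSET) where x is that gene's (nonnegative) value.
PROBE_OFFSET = 10.0


def prob_to_value(p: float) -> float:
    """Gene value that makes a stub classifier output probability p."""
    return PROBE_OFFSET + float(np.log(p / (1.0 - p)))


def make_stub_classifier(
    cell_type: str,
    gene: str,
    threshold: float = 0.5,
    parent: str | None = None,
) -> CellClassifier:
    model = LinearBinaryModel(
        feature_names=(gene,),
        weights=np.array([1.0]),
        intercept=0.0,
        platt_a=-1.0,
        platt_b=PROBE_OFFSET,
        feature_means=np.array([0.0]),
        feature_sds=np.array([1.0]),
    )
    return CellClassifier(cell_type=cell_type, model=model, threshold=threshold, parent=parent)


def matrix_from_dense(values, cell_ids=None, gene_ids=None, normalized=True) -> ExpressionMatrix:
    values = np.asarray(values, dtype=np.float64)
    n, g = values.shape
    return ExpressionMatrix(
        sp.csr_matrix(values),
        np.array(cell_ids if cell_ids is not None else [f"c{i}" for i in range(n)], dtype=object),
        np.array(gene_ids if gene_ids is not None else [f"g{j}" for j in range(g)], dtype=object),
        is_normalized=normalized,
    )


def probe_matrix(prob_rows: list[dict[str, float]], genes: list[str]) -> ExpressionMatrix:
    """Matrix where stub classifier for ``genes[j]`` outputs the given
    probability for each cell; unspecified genes get probability ~0."""
    vals = np.zeros((len(prob_rows), len(genes)))
    for i, row in enumerate(prob_rows):
        for j, g in enumerate(genes):
            vals[i, j] = prob_to_value(row.get(g, 1e-4))
    return matrix_from_dense(vals, gene_ids=genes)


@pytest.fixture
def two_root_db() -> ClassifierDatabase:
    db = ClassifierDatabase()
    db = add_classifier(db, make_stub_classifier("A", "gA"))
    db = add_classifier(db, make_stub_classifier("B", "gB"))
    return db


@pytest.fixture
def parent_child_db() -> ClassifierDatabase:
    db = ClassifierDatabase()
    db = add_classifier(db, make_stub_classifier("B cells", "gB"))
    db = add_classifier(db, make_stub_classifier("Plasma cells", "gP", parent="B cells"))
    return db
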