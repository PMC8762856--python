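"""Hierarchical classification of cells with ambiguity and rejection.

Root classifiers score every cell; a child classifier scores only cells
whose parent probability reached the parent threshold (the gate).  Per
cell, the final candidates are the deepest passing type on each passing
path — a passing child replaces its passing ancestor, since a subtype
call refines the lineage call.  Candidates from different branches stay,
giving an ambiguous slash-joined assignment; no candidate at all gives
``"unknown"``, which is how populations absent from the database are
rejected rather than forced into a label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .classifier_db import CellClassifier, ClassifierDatabase, validate_database
from .errors import DatabaseValidationError, ValidityError
from .preprocess import ExpressionMatrix, extract_features, normalize_counts, standardize

__all__ = ["PredictionTable", "predict_probability", "classify_cells", "set_threshold"]

UNKNOWN = "unknown"


@dataclass
class PredictionTable:
    """Per-cell probabilities and final assignments.

    ``probabilities`` is a cells x types frame in database order; NaN
    marks a type that was *not evaluated* for that cell (its parent's
    gate closed), which is deliberately distinct from a low probability.
    """

    cell_ids: np.ndarray
    probabilities: pd.DataFrame
    best_guess: np.ndarray
    assignment: np.ndarray
    thresholds: Optional[dict[str, float]] = None  # effective thresholds for this run

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def passing_sets(self) -> list[frozenset[str]]:
        """Per cell, the set of evaluated types whose probability met
        their (effective) threshold — before child-replaces-ancestor
        refinement."""
        if self.thresholds is None:
            raise ValidityError("this table was built without threshold information")
        cols = list(self.probabilities.columns)
        prob = self.probabilities.to_numpy()
        out = []
        for i in range(len(prob)):
            out.append(frozenset(
                t for j, t in enumerate(cols)
                if not np.isnan(prob[i, j]) and prob[i, j] >= self.thresholds[t]
            ))
        return out

    def assignment_sets(self) -> list[frozenset[str]]:
        """Candidate name set per cell (empty set for 'unknown')."""
        return [
            frozenset() if a == UNKNOWN else frozenset(a.split("/"))
            for a in self.assignment
        ]

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"cell_id": self.cell_ids,
                            "assignment": self.assignment,
                            "best_guess": self.best_guess})
        for col in self.probabilities.columns:
            out[f"p_{col}"] = self.probabilities[col].to_numpy()
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


def predict_probability(c: CellClassifier, m: ExpressionMatrix) -> np.ndarray:
    """Calibrated probability that each cell is of type ``c.cell_type``.

    Only the classifier's feature columns are densified; the rest of the
    matrix stays sparse.
    """
    if not m.is_normalized:
        raise ValidityError(
            "predict_probability expects a normalized matrix; call normalize_counts first"
        )
    fm = extract_features(m, c.features)
    fm = standardize(fm, c.model.feature_means, c.model.feature_sds)
    f = c.model.decision_values(fm.values)
    z = c.model.platt_a * f + c.model.platt_b
    with np.errstate(over="ignore"):
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
    # keep probabilities strictly inside (0, 1)
    eps = np.finfo(np.float64).tiny
    return np.clip(p, eps, 1.0 - 1e-16)


def classify_cells(
    db: ClassifierDatabase,
    m: ExpressionMatrix,
    threshold_overrides: Optional[Mapping[str, float]] = None,
    normalize_raw: bool = True,
) -> PredictionTable:
    """Apply a classifier database to every cell, parent-gated.

    ``threshold_overrides`` adjusts individual thresholds for this run
    only, without touching the stored models.
    """
    violations = validate_database(db)
    if violations:
        raise DatabaseValidationError("; ".join(violations))
    if m.n_cells == 0:
        raise ValidityError("expression matrix has no cells")
    overrides = dict(threshold_overrides or {})
    for name, thr in overrides.items():
        if name not in db:
            raise ValidityError(f"threshold override for unknown type {name!r}")
        if not (0.0 < thr < 1.0):
            raise ValidityError(f"threshold override for {name!r} out of (0, 1): {thr}")

    if not m.is_normalized:
        if not normalize_raw:
            raise ValidityError("matrix is not normalized and normalize_raw is off")
        m = normalize_counts(m)

    names = list(db.entries)
    thr_of = {n: overrides.get(n, db.entries[n].threshold) for n in names}
    probs = pd.DataFrame(np.nan, index=range(m.n_cells), columns=names, dtype=np.float64)
    passing = pd.DataFrame(False, index=range(m.n_cells), columns=names)

    # breadth-first over the forest so parents are always scored first
    frontier = db.roots()
    all_cells = np.arange(m.n_cells)
    gate_of: dict[str, np.ndarray] = {r: all_cells for r in frontier}
    while frontier:
        name = frontier.pop(0)
        cells = gate_of[name]
        if len(cells) > 0:
            p = predict_probability(db.entries[name], m.subset_cells(cells))
            probs.iloc[cells, probs.columns.get_loc(name)] = p
            ok = cells[p >= thr_of[name]]
        else:
            ok = cells
        passing.iloc[ok, passing.columns.get_loc(name)] = True
        for child in db.children(name):
            gate_of[child] = ok
            frontier.append(child)

    pass_mat = passing.to_numpy()
    # a passing type is a candidate unless one of its children also passes
    candidate = pass_mat.copy()
    for j, name in enumerate(names):
        kids = [names.index(k) for k in db.children(name)]
        if kids:
            covered = pass_mat[:, kids].any(axis=1)
            candidate[:, j] &= ~covered

    prob_mat = probs.to_numpy()
    assignment = np.empty(m.n_cells, dtype=object)
    best_guess = np.empty(m.n_cells, dtype=object)
    for i in range(m.n_cells):
        cand = [names[j] for j in np.flatnonzero(candidate[i])]
        if not cand:
            assignment[i] = UNKNOWN
            best_guess[i] = UNKNOWN
            continue
        cand_sorted = sorted(cand)
        assignment[i] = "/".join(cand_sorted)
        # highest probability wins; lexicographic tie-break
        best = min(cand_sorted, key=lambda n: (-prob_mat[i, names.index(n)], n))
        best_guess[i] = best

    probs.index = pd.Index(m.cell_ids, name="cell_id")
    return PredictionTable(
        cell_ids=np.asarray(m.cell_ids, dtype=object),
        probabilities=probs,
        best_guess=best_guess,
        assignment=assignment,
        thresholds=dict(thr_of),
    )


def set_threshold(db: ClassifierDatabase, cell_type: str, new_threshold: float) -> ClassifierDatabase:
    """Return a database where only this classifier's threshold changed."""
    return db.set_threshold(cell_type, new_threshold)
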