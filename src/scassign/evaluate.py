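"""Benchmark metrics: accuracy, per-type sensitivity/specificity,
unknown-population detection, ROC curves and threshold tuning.

Two scoring variants are supported.  Under ``strict`` scoring only an
unambiguous, exactly-matching assignment counts as correct.  Under
``intermediate_accepted`` scoring an assignment also counts when the
truth appears inside an ambiguous set, or when the assignment is a
single ancestor of the truth (calling a plasma cell "B cells" is
accepted as a correct intermediate classification).  Cells whose true
type is absent from the reference are correct exactly when rejected as
``"unknown"``; the unknown-population detection rate is the fraction of
such cells that were correctly left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .classifier_db import CellClassifier
from .classify import UNKNOWN, PredictionTable, predict_probability
from .errors import AlignmentError, DegenerateLabelsError, InfeasibleError, ValidityError
from .preprocess import ExpressionMatrix, normalize_counts

__all__ = [
    "MetricsReport",
    "score_predictions",
    "unknown_detection_rate",
    "roc_points",
    "tune_threshold",
]


@dataclass
class MetricsReport:
    accuracy: float
    per_type: dict[str, tuple[float, float]]
    mean_sensitivity: float
    mean_specificity: float
    unknown_detection_rate: Optional[float]
    variant: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": [self.variant],
                "accuracy": [self.accuracy],
                "mean_sensitivity": [self.mean_sensitivity],
                "mean_specificity": [self.mean_specificity],
                "unknown_detection_rate": [
                    np.nan if self.unknown_detection_rate is None else self.unknown_detection_rate
                ],
            }
        )

    def per_type_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t, s, sp) for t, (s, sp) in self.per_type.items()],
            columns=["cell_type", "sensitivity", "specificity"],
        )


def _align_truth(truth, preds: PredictionTable) -> np.ndarray:
    if isinstance(truth, Mapping):
        truth = pd.Series(truth)
    if isinstance(truth, pd.Series):
        missing = [c for c in preds.cell_ids if c not in truth.index]
        if missing:
            raise AlignmentError(f"{len(missing)} predicted cells missing from truth, e.g. {missing[:5]}")
        return truth.loc[list(preds.cell_ids)].to_numpy(dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(truth) != preds.n_cells:
        raise AlignmentError(f"{len(truth)} truth labels for {preds.n_cells} predicted cells")
    return truth


def _ancestors(t: str, hierarchy: Mapping[str, Optional[str]]) -> set[str]:
    out: set[str] = set()
    node = hierarchy.get(t)
    while node is not None and node not in out:
        out.add(node)
        node = hierarchy.get(node)
    return out


def _cell_correct(
    truth_label: str,
    assignment: str,
    reference_types: set[str],
    hierarchy: Mapping[str, Optional[str]],
    variant: str,
) -> bool:
    if truth_label not in reference_types:
        return assignment == UNKNOWN
    if variant == "strict":
        return assignment == truth_label
    names = set() if assignment == UNKNOWN else set(assignment.split("/"))
    if truth_label in names:
        return True
    # a single ancestor label is an accepted intermediate assignment
    return len(names) == 1 and next(iter(names)) in _ancestors(truth_label, hierarchy)


def score_predictions(
    truth,
    preds: PredictionTable,
    reference_types: set[str],
    hierarchy: Optional[Mapping[str, Optional[str]]] = None,
    variant: str = "strict",
    include_out_of_reference: bool = True,
) -> MetricsReport:
    """Score predictions against truth labels.

    ``reference_types`` are the types the classifier database knows;
    cells with other true labels should be rejected.  ``hierarchy`` maps
    each type to its parent and is only consulted by the
    ``intermediate_accepted`` variant.  ``include_out_of_reference``
    controls whether out-of-reference cells enter the accuracy
    denominator.
    """
    if variant not in ("strict", "intermediate_accepted"):
        raise ValidityError(f"unknown scoring variant {variant!r}")
    hierarchy = dict(hierarchy or {})
    reference_types = set(reference_types)
    y = _align_truth(truth, preds)

    correct = np.array(
        [
            _cell_correct(y[i], preds.assignment[i], reference_types, hierarchy, variant)
            for i in range(preds.n_cells)
        ]
    )
    if include_out_of_reference:
        accuracy = float(correct.mean()) if len(correct) else float("nan")
    else:
        in_ref = np.isin(y, list(reference_types))
        accuracy = float(correct[in_ref].mean()) if in_ref.any() else float("nan")

    assign_sets = preds.assignment_sets()
    per_type: dict[str, tuple[float, float]] = {}
    for t in sorted(reference_types):
        is_t = y == t
        if not is_t.any():
            continue
        sens = float(correct[is_t].mean())
        not_t = ~is_t
        # an ambiguous call naming t still asserts t
        asserts_t = np.array([t in s for s in assign_sets])
        spec = float((~asserts_t[not_t]).mean()) if not_t.any() else float("nan")
        per_type[t] = (sens, spec)

    sens_vals = [s for s, _ in per_type.values()]
    spec_vals = [sp for _, sp in per_type.values() if not np.isnan(sp)]
    return MetricsReport(
        accuracy=accuracy,
        per_type=per_type,
        mean_sensitivity=float(np.mean(sens_vals)) if sens_vals else float("nan"),
        mean_specificity=float(np.mean(spec_vals)) if spec_vals else float("nan"),
        unknown_detection_rate=unknown_detection_rate(y, preds, reference_types),
        variant=variant,
    )


def unknown_detection_rate(truth, preds: PredictionTable, reference_types: set[str]) -> Optional[float]:
    """Fraction of out-of-reference cells correctly left unassigned.

    Returns None when every cell's true type is in the reference.
    """
    y = _align_truth(truth, preds)
    out_of_ref = ~np.isin(y, list(set(reference_types)))
    if not out_of_ref.any():
        return None
    return float((preds.assignment[out_of_ref] == UNKNOWN).mean())


def _binary_probs(c: CellClassifier, m: ExpressionMatrix, truth) -> tuple[np.ndarray, np.ndarray]:
    if not m.is_normalized:
        m = normalize_counts(m)
    p = predict_probability(c, m)
    y = np.asarray(truth, dtype=object)
    if len(y) != m.n_cells:
        raise AlignmentError(f"{len(y)} truth labels for {m.n_cells} cells")
    pos = y == c.cell_type
    if pos.all() or not pos.any():
        raise DegenerateLabelsError(
            f"truth contains a single class relative to {c.cell_type!r}"
        )
    return p, pos


def roc_points(
    c: CellClassifier, m: ExpressionMatrix, truth
) -> tuple[list[tuple[float, float, float]], float]:
    """ROC curve of one classifier against binary truth.

    Returns ``(points, auc)`` where points are ``(threshold, tpr, fpr)``
    at every unique predicted probability (rule: assign when
    ``p >= threshold``) and the area is the trapezoid over the curve
    anchored at (0, 0).
    """
    p, pos = _binary_probs(c, m, truth)
    thresholds = np.unique(p)[::-1]  # descending: curve runs (0,0) -> (1,1)
    n_pos = int(pos.sum())
    n_neg = int(len(pos) - n_pos)
    points = []
    for thr in thresholds:
        called = p >= thr
        tpr = float((called & pos).sum() / n_pos)
        fpr = float((called & ~pos).sum() / n_neg)
        points.append((float(thr), tpr, fpr))
    fprs = np.concatenate([[0.0], [pt[2] for pt in points]])
    tprs = np.concatenate([[0.0], [pt[1] for pt in points]])
    auc = float(np.trapezoid(tprs, fprs))
    return points, auc


def tune_threshold(
    c: CellClassifier,
    m: ExpressionMatrix,
    truth,
    objective: str = "youden",
    target_sensitivity: Optional[float] = None,
) -> float:
    """Pick a probability threshold from the data.

    ``youden`` maximizes tpr - fpr (ties: lowest threshold);
    ``target_sensitivity`` returns the largest threshold still reaching
    the requested sensitivity.
    """
    points, _ = roc_points(c, m, truth)
    if objective == "youden":
        best = max(points, key=lambda pt: (pt[1] - pt[2], pt[0]))
        # ties prefer the lowest threshold
        best_j = best[1] - best[2]
        candidates = [pt[0] for pt in points if (pt[1] - pt[2]) == best_j]
        return float(min(candidates))
    if objective == "target_sensitivity":
        if target_sensitivity is None:
            raise ValidityError("target_sensitivity objective requires a target value")
        feasible = [pt[0] for pt in points if pt[1] >= target_sensitivity]
        if not feasible:
            raise InfeasibleError(
                f"no threshold reaches sensitivity {target_sensitivity}"
            )
        return float(max(feasible))
    raise ValidityError(f"unknown objective {objective!r}")
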