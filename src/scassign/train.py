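"""Training of binary, probability-calibrated linear cell-type classifiers.

Each cell type gets one soft-margin linear SVM separating that type from
all other cells (one-vs-rest).  When a parent type is given, training is
restricted to cells of the parent lineage, so the child model learns to
split the parent population rather than the whole dataset.  Decision
values are mapped to probabilities by Platt scaling: a sigmoid
``p = 1/(1 + exp(A f + B))`` fitted by regularized maximum likelihood on
the training decision values, using Platt's smoothed targets
``t+ = (N+ + 1)/(N+ + 2)`` and ``t- = 1/(N- + 2)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.svm import SVC

from .classifier_db import (
    CellClassifier,
    ClassifierDatabase,
    LinearBinaryModel,
    add_classifier,
)
from .errors import (
    DegenerateFeaturesError,
    DegenerateLabelsError,
    OptimizationError,
    SampleSizeError,
    UnresolvedParentError,
    ValidityError,
)
from .preprocess import (
    ExpressionMatrix,
    FeatureMatrix,
    extract_features,
    normalize_counts,
    standardize,
)

__all__ = [
    "TrainingConfig",
    "make_binary_labels",
    "balance_downsample",
    "fit_linear_svm",
    "calibrate_platt",
    "train_classifier",
    "train_database",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Adjustable training parameters.

    ``cost_c`` is the soft-margin cost (regularization strength 1/C);
    ``balance='downsample'`` subsamples the majority class to the
    minority size before fitting, which matters because one-vs-rest
    labels are extremely imbalanced for rare types.
    """

    kernel: str = "linear"
    cost_c: float = 1.0
    balance: str = "downsample"
    seed: int = 0
    min_cells_per_class: int = 10

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValidityError(f"only the linear kernel is supported, got {self.kernel!r}")
        if self.cost_c <= 0:
            raise ValidityError("cost_c must be positive")
        if self.balance not in ("downsample", "none"):
            raise ValidityError(f"unknown balance mode {self.balance!r}")
        if self.min_cells_per_class < 2:
            raise ValidityError("min_cells_per_class must be >= 2")


def make_binary_labels(
    labels: Sequence[str],
    positive_type: str,
    aliases: Optional[set[str]] = None,
) -> np.ndarray:
    """One-vs-rest labels: +1 for ``positive_type`` (or an alias), -1 otherwise."""
    labels = np.asarray(labels, dtype=object)
    positives = {positive_type} | (set(aliases) if aliases else set())
    y = np.where(np.isin(labels, list(positives)), 1, -1).astype(np.int64)
    n_pos = int((y == 1).sum())
    if n_pos == 0 or n_pos == len(y):
        raise DegenerateLabelsError(
            f"binary labeling for {positive_type!r} produced a single class "
            f"({n_pos} of {len(y)} positive)"
        )
    return y


def balance_downsample(y: np.ndarray, seed: int) -> np.ndarray:
    """Indices keeping all minority-class cells and a seeded random
    majority subsample of equal size; returned sorted."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == -1)
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateLabelsError("both classes must be present to balance")
    rng = np.random.default_rng(seed)
    if len(pos) == len(neg):
        return np.sort(np.concatenate([pos, neg]))
    minority, majority = (pos, neg) if len(pos) < len(neg) else (neg, pos)
    keep = rng.choice(majority, size=len(minority), replace=False)
    return np.sort(np.concatenate([minority, keep]))


def fit_linear_svm(X: np.ndarray, y: np.ndarray, cost_c: float = 1.0) -> tuple[np.ndarray, float]:
    """Soft-margin linear SVM (hinge loss, L2 penalty, strength 1/C).

    Returns ``(weights, intercept)`` with the decision value
    ``f(x) = w . x + b`` positive toward the +1 class.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValidityError(f"X shape {X.shape} does not match {len(y)} labels")
    stds = X.std(axis=0)
    if np.any(stds == 0):
        raise DegenerateFeaturesError(
            f"{int((stds == 0).sum())} constant column(s) in the training matrix"
        )
    svm = SVC(kernel="linear", C=cost_c, tol=1e-6)
    svm.fit(X, y)
    if hasattr(svm, "fit_status_") and svm.fit_status_ != 0:
        raise OptimizationError("SVM solver reached its iteration cap without converging")
    w = np.asarray(svm.coef_).ravel().astype(np.float64)
    b = float(svm.intercept_[0])
    # libsvm orients the decision function toward classes_[1]; with labels
    # in {-1, +1} that is +1 already, but guard against other encodings
    if svm.classes_[1] != 1:
        w, b = -w, -b
    return w, b


def _platt_objective(ab: np.ndarray, f: np.ndarray, t: np.ndarray) -> float:
    z = ab[0] * f + ab[1]
    # numerically stable cross entropy of sigmoid(-z) against targets t
    return float(np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                                 (t - 1.0) * z + np.log1p(np.exp(z)))))


def calibrate_platt(
    decision_values: np.ndarray,
    y: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[float, float]:
    """Fit Platt's sigmoid ``p(f) = 1/(1 + exp(A f + B))`` by Newton descent.

    Minimizes the negative log likelihood with Platt's smoothed targets.
    ``A`` comes out negative whenever decision values are positively
    associated with the +1 class.
    """
    f = np.asarray(decision_values, dtype=np.float64).ravel()
    y = np.asarray(y).ravel()
    if len(f) != len(y):
        raise ValidityError("decision_values and y have different lengths")
    n_pos = int((y == 1).sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DegenerateLabelsError("both classes are required for calibration")
    hi = (n_pos + 1.0) / (n_pos + 2.0)
    lo = 1.0 / (n_neg + 2.0)
    t = np.where(y == 1, hi, lo)

    sigma = 1e-12  # Hessian ridge
    a = 0.0
    b = float(np.log((n_neg + 1.0) / (n_pos + 1.0)))
    fval = _platt_objective(np.array([a, b]), f, t)
    for _ in range(max_iter):
        z = a * f + b
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        d1 = t - p  # dNLL/dz per point
        d2 = p * (1.0 - p)
        g_a = float(np.sum(d1 * f))
        g_b = float(np.sum(d1))
        if abs(g_a) < tol and abs(g_b) < tol:
            break
        h11 = float(np.sum(d2 * f * f)) + sigma
        h22 = float(np.sum(d2)) + sigma
        h12 = float(np.sum(d2 * f))
        det = h11 * h22 - h12 * h12
        if det <= 0:
            raise OptimizationError("Platt Hessian is singular")
        da = -(h22 * g_a - h12 * g_b) / det
        db = -(-h12 * g_a + h11 * g_b) / det
        # backtracking line search on the Newton direction
        step = 1.0
        gd = g_a * da + g_b * db
        while step >= 1e-10:
            new_a, new_b = a + step * da, b + step * db
            new_f = _platt_objective(np.array([new_a, new_b]), f, t)
            if new_f < fval + 1e-4 * step * gd:
                a, b, fval = new_a, new_b, new_f
                break
            step /= 2.0
        else:
            break
    else:
        raise OptimizationError(f"Platt calibration did not converge in {max_iter} iterations")
    return float(a), float(b)


def train_classifier(
    m: ExpressionMatrix,
    labels: Sequence[str],
    cell_type: str,
    features: Sequence[str],
    cfg: TrainingConfig = TrainingConfig(),
    parent_db: Optional[ClassifierDatabase] = None,
    parent: Optional[str] = None,
    positive_aliases: Optional[set[str]] = None,
    lineage_labels: Optional[set[str]] = None,
) -> CellClassifier:
    """Train one cell type's calibrated classifier.

    Pipeline: restrict to parent-lineage cells (labels, not parent
    predictions) -> normalize raw counts -> extract the feature block ->
    drop constant features -> z-score (storing the constants) -> balance
    classes -> fit the linear SVM -> Platt-calibrate on the training
    decision values.

    ``positive_aliases`` are additional label spellings (or descendant
    labels) counted as the positive class.  ``lineage_labels`` overrides
    the set of labels considered part of the parent lineage; by default
    it is the parent, its descendants already in ``parent_db``, the new
    type itself, and any aliases.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != m.n_cells:
        raise ValidityError(f"{len(labels)} labels for {m.n_cells} cells")

    if parent is not None:
        if parent_db is None or parent not in parent_db:
            raise UnresolvedParentError(f"parent {parent!r} is not in the classifier database")
        if lineage_labels is None:
            lineage_labels = (
                {parent, cell_type}
                | set(parent_db.descendants(parent))
                | (set(positive_aliases) if positive_aliases else set())
            )
        mask = np.isin(labels, list(lineage_labels))
        if int(mask.sum()) < 2 * cfg.min_cells_per_class:
            raise SampleSizeError(
                f"only {int(mask.sum())} cells carry parent-lineage labels "
                f"{sorted(lineage_labels)}; need at least {2 * cfg.min_cells_per_class}"
            )
        m = m.subset_cells(np.flatnonzero(mask))
        labels = labels[mask]

    if not m.is_normalized:
        m = normalize_counts(m)

    fm = extract_features(m, features)
    means = fm.values.mean(axis=0)
    sds = fm.values.std(axis=0, ddof=0)
    keep = sds > 0
    if not keep.any():
        raise DegenerateFeaturesError(
            f"all {len(features)} features are constant on the training cells"
        )
    if not keep.all():
        dropped = [f for f, k in zip(fm.feature_names, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} constant feature(s) before fitting: {dropped}",
            stacklevel=2,
        )
    kept_names = tuple(f for f, k in zip(fm.feature_names, keep) if k)
    fm = FeatureMatrix(fm.values[:, keep], fm.cell_ids, kept_names,
                       tuple(f for f in fm.missing_features if f in kept_names))
    means, sds = means[keep], sds[keep]
    fm = standardize(fm, means, sds)

    y = make_binary_labels(labels, cell_type, positive_aliases)
    if cfg.balance == "downsample":
        idx = balance_downsample(y, cfg.seed)
    else:
        idx = np.arange(len(y))
    y_fit = y[idx]
    x_fit = fm.values[idx]
    n_pos = int((y_fit == 1).sum())
    n_neg = int((y_fit == -1).sum())
    if n_pos < cfg.min_cells_per_class or n_neg < cfg.min_cells_per_class:
        raise SampleSizeError(
            f"training {cell_type!r} needs >= {cfg.min_cells_per_class} cells per class, "
            f"got {n_pos} positive / {n_neg} negative"
        )

    w, b = fit_linear_svm(x_fit, y_fit, cfg.cost_c)
    # calibrate on all lineage-restricted training cells, not only the
    # balanced subset: the extra majority-class cells were unseen by the
    # margin fit and anchor the sigmoid where the classes actually mix
    decisions = fm.values @ w + b
    platt_a, platt_b = calibrate_platt(decisions, y)

    model = LinearBinaryModel(
        feature_names=kept_names,
        weights=w,
        intercept=b,
        platt_a=platt_a,
        platt_b=platt_b,
        feature_means=means,
        feature_sds=sds,
    )
    return CellClassifier(cell_type=cell_type, model=model, threshold=0.5, parent=parent)


def train_database(
    m: ExpressionMatrix,
    labels: Sequence[str],
    hierarchy: Mapping[str, Optional[str]],
    features: Mapping[str, Sequence[str]],
    cfg: TrainingConfig = TrainingConfig(),
) -> ClassifierDatabase:
    """Train a classifier for every type in ``hierarchy`` (name -> parent).

    Types are trained parents-first.  A type's positive class includes
    all its descendant labels (a plasma cell is also a B cell); a child
    is trained only on cells of its parent's lineage.
    """
    hierarchy = dict(hierarchy)
    for name, parent in hierarchy.items():
        if parent is not None and parent not in hierarchy:
            raise UnresolvedParentError(f"parent {parent!r} of {name!r} is not being trained")

    def descendants(t: str) -> set[str]:
        out: set[str] = set()
        frontier = [n for n, p in hierarchy.items() if p == t]
        while frontier:
            n = frontier.pop()
            out.add(n)
            frontier.extend(c for c, p in hierarchy.items() if p == n)
        return out

    db = ClassifierDatabase()
    remaining = dict(hierarchy)
    while remaining:
        ready = [n for n, p in remaining.items() if p is None or p in db]
        if not ready:
            raise ValidityError(f"hierarchy contains a cycle among {sorted(remaining)}")
        for name in ready:
            parent = remaining.pop(name)
            lineage = None
            if parent is not None:
                lineage = {parent} | descendants(parent)
            c = train_classifier(
                m, labels, name, features[name], cfg,
                parent_db=db if parent is not None else None,
                parent=parent,
                positive_aliases=descendants(name) or None,
                lineage_labels=lineage,
            )
            db = add_classifier(db, c)
    return db
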