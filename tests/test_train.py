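"""Training: labeling, balancing, the SVM fit against a QP oracle,
Platt calibration against a direct minimizer, and the full pipeline."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
import scipy.optimize

from scassign import (
    TrainingConfig,
    balance_downsample,
    calibrate_platt,
    fit_linear_svm,
    make_binary_labels,
    train_classifier,
)
from scassign.errors import (
    DegenerateFeaturesError,
    DegenerateLabelsError,
    SampleSizeError,
    UnresolvedParentError,
    ValidityError,
)
from scassign.preprocess import extract_features, normalize_counts, standardize
from scassign.classify import predict_probability
from scassign.synthetic import SimulationSpec, TypeSpec, gene_names, simulate_dataset
from scassign.classifier_db import ClassifierDatabase, add_classifier
from tests.conftest import make_stub_classifier

# ---------------------------------------------------------------- labels


def test_make_binary_labels_basic_and_aliases():
    y = make_binary_labels(["B", "T", "B", "NK"], "B")
    assert list(y) == [1, -1, 1, -1]
    y = make_binary_labels(["B cell", "B cells", "T"], "B cells", aliases={"B cell"})
    assert list(y) == [1, 1, -1]
    with pytest.raises(DegenerateLabelsError):
        make_binary_labels(["B", "B"], "B")
    with pytest.raises(DegenerateLabelsError):
        make_binary_labels(["T", "NK"], "B")


def test_balance_downsample_contract():
    y = np.array([1] * 10 + [-1] * 10)
    assert len(balance_downsample(y, 0)) == 20  # already balanced: keep all
    y = np.array([1] * 5 + [-1] * 100)
    idx = balance_downsample(y, 7)
    assert len(idx) == 10
    assert (y[idx] == 1).sum() == 5 and (y[idx] == -1).sum() == 5
    assert set(np.flatnonzero(y == 1)) <= set(idx)  # minority fully retained
    assert np.array_equal(idx, balance_downsample(y, 7))  # seeded determinism
    assert not np.array_equal(idx, balance_downsample(y, 8))


# ---------------------------------------------------------------- SVM


def _qp_svm_oracle(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Brute-force dual soft-margin SVM via constrained optimization."""
    n = len(y)
    K = (X * y[:, None]) @ (X * y[:, None]).T

    def neg_dual(a):
        return 0.5 * a @ K @ a - a.sum()

    res = scipy.optimize.minimize(
        neg_dual,
        np.full(n, min(C, 1.0) / 2),
        jac=lambda a: K @ a - 1.0,
        bounds=[(0.0, C)] * n,
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}],
        method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    assert res.success
    a = res.x
    w = ((a * y)[:, None] * X).sum(axis=0)
    on_margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    b = float(np.mean(y[on_margin] - X[on_margin] @ w))
    return w, b


def test_fit_linear_svm_symmetric_pair():
    X = np.array([[-1.0], [1.0]])
    y = np.array([-1, 1])
    w, b = fit_linear_svm(X, y, cost_c=1.0)
    assert w[0] > 0
    assert np.sign(X @ w + b).tolist() == [-1.0, 1.0]


def test_fit_linear_svm_label_flip_negates_solution():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(-2, 0.5, (8, 2)), rng.normal(2, 0.5, (8, 2))])
    y = np.array([-1] * 8 + [1] * 8)
    w, b = fit_linear_svm(X, y, cost_c=1.0)
    w2, b2 = fit_linear_svm(X, -y, cost_c=1.0)
    assert np.allclose(w2, -w, atol=1e-6)
    assert np.isclose(b2, -b, atol=1e-6)


@pytest.mark.parametrize("case", range(4))
def test_fit_linear_svm_matches_qp_oracle(case):
    """On small 2-D separable sets the normalized weight vector matches a
    brute-force quadratic-programming solution."""
    sets = [
        (np.array([[0.0, 0.0], [0.0, 1.0], [2.0, 0.0], [2.0, 1.0]]),
         np.array([-1, -1, 1, 1])),
        (np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 2.0], [4.0, 4.0], [0.5, 0.2], [3.5, 3.0]]),
         np.array([-1, -1, 1, 1, -1, 1])),
        (np.array([[-1.0, -1.0], [-2.0, 0.5], [-1.5, 1.0], [1.0, 1.0], [2.0, -0.5], [1.5, 0.3]]),
         np.array([-1, -1, -1, 1, 1, 1])),
        (np.array([[0.0, 1.0], [1.0, 2.0], [0.5, 0.8], [2.5, 0.0], [3.0, 1.0],
                   [2.8, -0.5], [0.2, 1.5], [3.3, 0.4]]),
         np.array([-1, -1, -1, 1, 1, 1, -1, 1])),
    ]
    X, y = sets[case]
    C = 10.0
    w, b = fit_linear_svm(X, y, cost_c=C)
    w_oracle, b_oracle = _qp_svm_oracle(X, y, C)
    assert np.allclose(w / np.linalg.norm(w), w_oracle / np.linalg.norm(w_oracle), atol=1e-4)
    assert np.isclose(b / np.linalg.norm(w), b_oracle / np.linalg.norm(w_oracle), atol=1e-3)


def test_fit_linear_svm_rejects_constant_columns():
    X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]])
    with pytest.raises(DegenerateFeaturesError):
        fit_linear_svm(X, np.array([-1, -1, 1, 1]))


# ---------------------------------------------------------------- Platt

PLATT_6PT_F = np.array([-2.0, -1.2, -0.3, 0.4, 1.1, 2.2])
PLATT_6PT_Y = np.array([-1, -1, 1, -1, 1, 1])


def _platt_nll(a, b, f, y):
    n_pos = (y == 1).sum()
    n_neg = (y == -1).sum()
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    z = a * f + b
    return np.sum(np.where(z >= 0, t * z + np.log1p(np.exp(-z)),
                           (t - 1.0) * z + np.log1p(np.exp(z))))


def _platt_oracle(f, y):
    """Coarse grid over (A, B) followed by simplex refinement."""
    grid_a = np.linspace(-15.0, 2.0, 120)
    grid_b = np.linspace(-6.0, 6.0, 100)
    vals = [((a, b), _platt_nll(a, b, f, y)) for a in grid_a for b in grid_b]
    (a0, b0), _ = min(vals, key=lambda kv: kv[1])
    res = scipy.optimize.minimize(
        lambda ab: _platt_nll(ab[0], ab[1], f, y),
        np.array([a0, b0]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10000},
    )
    return float(res.x[0]), float(res.x[1])


def test_calibrate_platt_matches_grid_refinement_oracle():
    a, b = calibrate_platt(PLATT_6PT_F, PLATT_6PT_Y)
    a_star, b_star = _platt_oracle(PLATT_6PT_F, PLATT_6PT_Y)
    assert np.isclose(a, a_star, atol=1e-4)
    assert np.isclose(b, b_star, atol=1e-4)
    assert a < 0  # decision values positively associated with +1


def test_calibrate_platt_symmetry_gives_zero_offset():
    f = np.array([-1.0, 1.0, -1.0, 1.0])
    y = np.array([-1, 1, -1, 1])
    a, b = calibrate_platt(f, y)
    assert abs(b) < 1e-6
    assert a < 0


def test_calibrate_platt_probability_monotone():
    a, b = calibrate_platt(PLATT_6PT_F, PLATT_6PT_Y)
    f = np.linspace(-5, 5, 200)
    p = 1.0 / (1.0 + np.exp(a * f + b))
    assert np.all(np.diff(p) > 0)


def test_calibrate_platt_single_class_error():
    with pytest.raises(DegenerateLabelsError):
        calibrate_platt(np.array([0.1, 0.2]), np.array([1, 1]))


# ---------------------------------------------------------------- pipeline


def _two_type_spec(seed=0, fold=4.0):
    genes = gene_names(60)
    return SimulationSpec(
        types=(
            TypeSpec("Alpha", None, 120, tuple(genes[:15]), fold),
            TypeSpec("Beta", None, 120, tuple(genes[15:30]), fold),
        ),
        n_genes=60,
        seed=seed,
    )


def test_train_classifier_strong_markers_high_training_accuracy():
    m, labels = simulate_dataset(_two_type_spec())
    feats = gene_names(60)[:30]
    c = train_classifier(m, labels, "Alpha", feats, TrainingConfig(seed=1))
    p = predict_probability(c, normalize_counts(m))
    acc = (((p >= 0.5) & (labels == "Alpha")) | ((p < 0.5) & (labels != "Alpha"))).mean()
    assert acc >= 0.95
    assert c.threshold == 0.5 and c.parent is None


def test_train_classifier_deterministic():
    m, labels = simulate_dataset(_two_type_spec())
    feats = gene_names(60)[:30]
    c1 = train_classifier(m, labels, "Alpha", feats, TrainingConfig(seed=5))
    c2 = train_classifier(m, labels, "Alpha", feats, TrainingConfig(seed=5))
    assert c1.equals(c2)


def test_train_classifier_calibration_sanity():
    """Mean calibrated probability over the balanced training cells stays
    near the balanced positive fraction (0.5)."""
    m, labels = simulate_dataset(_two_type_spec())
    feats = gene_names(60)[:30]
    c = train_classifier(m, labels, "Alpha", feats, TrainingConfig(seed=1))
    p = predict_probability(c, normalize_counts(m))
    assert abs(p.mean() - 0.5) < 0.1


def test_child_training_restricted_to_parent_lineage():
    """Cells outside the parent lineage never influence a child fit: the
    negative class is the parent's other cells, and removing unrelated
    cells changes nothing."""
    genes = gene_names(80)
    spec = SimulationSpec(
        types=(
            TypeSpec("B cells", None, 150, tuple(genes[:15]), 4.0),
            TypeSpec("T cells", None, 150, tuple(genes[15:30]), 4.0),
            TypeSpec("Plasma cells", "B cells", 150, tuple(genes[30:45]), 4.0),
        ),
        n_genes=80,
        seed=11,
    )
    m, labels = simulate_dataset(spec)
    parent_db = ClassifierDatabase()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parent_db = add_classifier(
            parent_db,
            train_classifier(m, labels, "B cells", genes[:45], TrainingConfig(seed=2),
                             positive_aliases={"Plasma cells"}),
        )
        child = train_classifier(
            m, labels, "Plasma cells", genes[30:45], TrainingConfig(seed=2),
            parent_db=parent_db, parent="B cells",
        )
        # drop all T cells: the child fit must be bit-identical
        keep = np.flatnonzero(labels != "T cells")
        child2 = train_classifier(
            m.subset_cells(keep), labels[keep], "Plasma cells", genes[30:45],
            TrainingConfig(seed=2), parent_db=parent_db, parent="B cells",
        )
    assert child.parent == "B cells"
    assert child.equals(child2)


def test_train_classifier_errors():
    m, labels = simulate_dataset(_two_type_spec())
    feats = gene_names(60)[:30]
    with pytest.raises(UnresolvedParentError):
        train_classifier(m, labels, "Alpha", feats, parent_db=ClassifierDatabase(),
                         parent="Missing")
    with pytest.raises(SampleSizeError):
        train_classifier(m, labels, "Alpha", feats,
                         TrainingConfig(min_cells_per_class=1000))


def test_training_config_validation():
    with pytest.raises(ValidityError):
        TrainingConfig(kernel="rbf")
    with pytest.raises(ValidityError):
        TrainingConfig(cost_c=-1.0)
    with pytest.raises(ValidityError):
        TrainingConfig(min_cells_per_class=1)
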